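"""Synthetic genomes, annotations, stranded read sets and expression tables.

The generator emulates the data regimes the analysis assumes: a toy
genome with promoter-planted GC skew and CpG islands; non-overlapping
coding genes plus divergent head-to-head pairs; strand-specific fragment
sets with planted long upstream antisense transcripts (LUATs), uniform
background noise and a co-transcriptional pre-mRNA component; and
multi-tissue FPKM matrices with controlled LUAT/gene correlation.  Every
output is deterministic given the configuration seed, and each stage
emits a ground-truth table so downstream estimators can be scored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import FeatureIntervals, GenomeAssembly, StrandedReadSet, TranscriptModel

__all__ = [
    "GenomeConfig",
    "AnnotationConfig",
    "ExpressionConfig",
    "TissueConfig",
    "SimConfig",
    "simulate_genome",
    "simulate_annotation",
    "simulate_reads",
    "simulate_multitissue",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
GENE_CLASSES = ("luat_associated", "coding_coding", "unidirectional")


@dataclass
class GenomeConfig:
    n_chroms: int = 4
    chrom_length: int = 15_000_000
    gc: float = 0.42
    cpg_depletion: float = 0.8        # fraction of background CpG dinucleotides lost (C->T)
    skew_amplitude: float = 0.3       # planted G-vs-C excess downstream of LUAT promoters
    skew_extent: int = 1000           # bp of planted skew on each side of the TSS
    cpg_island_prob: dict = field(
        default_factory=lambda: {
            "luat_associated": 0.80,
            "coding_coding": 0.89,
            "unidirectional": 0.56,
        }
    )
    cpg_island_median_bp: int = 1000
    cpg_island_sigma: float = 0.4


@dataclass
class AnnotationConfig:
    n_genes: int = 200
    luat_fraction: float = 0.25       # genes with a planted LUAT
    head_to_head_fraction: float = 0.10  # genes living in divergent coding pairs
    head_to_head_sep: tuple = (300, 1400)  # TSS separation range, bp
    n_exons: int = 6
    exon_length: int = 200
    intron_length: int = 1000
    first_exon_median: dict = field(
        default_factory=lambda: {
            "luat_associated": 242,
            "coding_coding": 195,
            "unidirectional": 190,
        }
    )
    first_exon_sigma: float = 0.45
    intergene_gap: tuple = (12_000, 25_000)  # uniform spacing between gene units


@dataclass
class ExpressionConfig:
    library_size: int = 20_000_000    # mapped fragments
    fragment_length: int = 100
    gene_fpkm_median: float = 8.0
    gene_fpkm_sigma: float = 1.0
    luat_fpkm_median: float = 4.0
    luat_fpkm_sigma: float = 0.5
    luat_fpkm_min: float = 2.0
    luat_length_median: int = 2000
    luat_length_sigma: float = 0.5
    luat_length_range: tuple = (800, 6000)
    luat_offset_mean: int = 580       # exponential 5'-offset scale; 58% within 500 bp
    luat_offset_max: int = 1400
    background_per_kb: float = 0.2    # noise fragments per kb per strand
    premrna_fraction: float = 0.3     # unspliced co-transcriptional fraction (Total RNA regime)
    intron1_retention: float = 0.0    # extra fraction of molecules retaining intron 1 only


@dataclass
class TissueConfig:
    n_conditions: int = 17
    n_pairs: int = 200
    pair_correlation: float = 0.8
    specific_fraction: float = 0.3    # genes boosted in exactly one tissue
    specific_fold: float = 8.0
    base_fpkm_median: float = 5.0
    base_fpkm_sigma: float = 0.5


@dataclass
class SimConfig:
    seed: int
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    tissues: TissueConfig = field(default_factory=TissueConfig)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for frac in (
            self.annotation.luat_fraction,
            self.annotation.head_to_head_fraction,
            self.expression.premrna_fraction,
            self.expression.intron1_retention,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction out of [0,1]: {frac}")
        if abs(self.tissues.pair_correlation) > 1:
            raise ValueError("|pair_correlation| must be <= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, sub in (
            ("genome", GenomeConfig),
            ("annotation", AnnotationConfig),
            ("expression", ExpressionConfig),
            ("tissues", TissueConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d[key].items()})
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _lognormal(rng, median: float, sigma: float, size=None):
    return np.exp(rng.normal(np.log(median), sigma, size=size))


# ---------------------------------------------------------------------------
# locus plan (shared between genome and annotation synthesis)

@dataclass
class _Locus:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_class: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]


def _gene_exons(tss: int, strand: str, first_exon_len: int, cfg: AnnotationConfig):
    """Exon intervals for a gene whose 5' exon has the given length."""
    sizes = [first_exon_len] + [cfg.exon_length] * (cfg.n_exons - 1)
    exons = []
    if strand == "+":
        pos = tss
        for sz in sizes:
            exons.append((pos, pos + sz))
            pos += sz + cfg.intron_length
    else:
        pos = tss + 1
        for sz in sizes:
            exons.append((pos - sz, pos))
            pos -= sz + cfg.intron_length
        exons.reverse()
    return tuple(exons)


def plan_loci(config: SimConfig) -> list[_Locus]:
    """Deterministic gene layout: classes, strands, TSS positions, exon
    structures.  Genes are laid left-to-right with intergenic gaps large
    enough to keep every non-head-to-head upstream 5 kb region clear."""
    acf = config.annotation
    rng = _rng(config, 1)

    n = acf.n_genes
    n_luat = int(round(n * acf.luat_fraction))
    n_h2h = int(round(n * acf.head_to_head_fraction))
    n_h2h -= n_h2h % 2  # pairs
    classes = (
        ["luat_associated"] * n_luat
        + ["coding_coding"] * n_h2h
        + ["unidirectional"] * (n - n_luat - n_h2h)
    )
    rng.shuffle(classes)

    chrom_names = [f"chr{i + 1}" for i in range(config.genome.n_chroms)]
    gene_len = acf.exon_length * acf.n_exons + acf.intron_length * (acf.n_exons - 1) + 400

    loci: list[_Locus] = []
    cursors = {c: 20_000 for c in chrom_names}
    chrom_i = 0
    gid = 0
    pending_h2h = [c for c in classes if c == "coding_coding"]
    singles = [c for c in classes if c != "coding_coding"]
    units: list[list[str]] = [[c] for c in singles]
    units += [["coding_coding", "coding_coding"]
              for _ in range(len(pending_h2h) // 2)]
    order = rng.permutation(len(units))

    for ui in order:
        unit = units[ui]
        chrom = chrom_names[chrom_i % len(chrom_names)]
        chrom_i += 1
        gap = int(rng.integers(acf.intergene_gap[0], acf.intergene_gap[1]))
        start = cursors[chrom] + gap
        if len(unit) == 1:
            strand = str(rng.choice(["+", "-"]))
            fe = int(np.clip(_lognormal(rng, acf.first_exon_median[unit[0]],
                                        acf.first_exon_sigma), 50, 3000))
            tss = start if strand == "+" else start + gene_len - 1
            exons = _gene_exons(tss, strand, fe, acf)
            span = (exons[0][0], exons[-1][1])
            loci.append(_Locus(f"g{gid:04d}", chrom, strand, tss, unit[0], span, exons))
            gid += 1
            cursors[chrom] = span[1]
        else:
            # divergent pair: minus-strand gene reading left, plus-strand reading right
            sep = int(rng.integers(*acf.head_to_head_sep))
            fe1 = int(np.clip(_lognormal(rng, acf.first_exon_median["coding_coding"],
                                         acf.first_exon_sigma), 50, 3000))
            fe2 = int(np.clip(_lognormal(rng, acf.first_exon_median["coding_coding"],
                                         acf.first_exon_sigma), 50, 3000))
            tss_minus = start + gene_len - 1
            exons_m = _gene_exons(tss_minus, "-", fe1, acf)
            tss_plus = tss_minus + sep
            exons_p = _gene_exons(tss_plus, "+", fe2, acf)
            loci.append(_Locus(f"g{gid:04d}", chrom, "-", tss_minus,
                               "coding_coding", (exons_m[0][0], exons_m[-1][1]), exons_m))
            gid += 1
            loci.append(_Locus(f"g{gid:04d}", chrom, "+", tss_plus,
                               "coding_coding", (exons_p[0][0], exons_p[-1][1]), exons_p))
            gid += 1
            cursors[chrom] = exons_p[-1][1]

    for chrom, cur in cursors.items():
        if cur > config.genome.chrom_length - 20_000:
            raise ValueError(
                f"infeasible packing on {chrom}: need {cur + 20_000} bp, "
                f"have {config.genome.chrom_length}; reduce n_genes or enlarge genome"
            )
    return loci


# ---------------------------------------------------------------------------
# genome

def _random_bases(rng, n: int, gc: float, skew: float = 0.0) -> np.ndarray:
    """i.i.d. bases as uint8 ASCII; ``skew`` biases G vs C as (pG-pC)/(pG+pC)."""
    p_g = gc / 2 * (1 + skew)
    p_c = gc - p_g
    p = np.array([(1 - gc) / 2, p_c, p_g, (1 - gc) / 2])  # A, C, G, T
    edges = np.cumsum(p)
    u = rng.random(n)
    codes = np.searchsorted(edges, u, side="right").clip(0, 3)
    return _BASES[codes]


def _cpg_block(rng, n: int) -> np.ndarray:
    """CpG-dense, GC-rich sequence of length ``n`` (uint8 ASCII)."""
    out = np.empty(n + 1, dtype=np.uint8)
    i = 0
    while i < n:
        if rng.random() < 0.2:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            u = rng.random()
            out[i] = ord("ACGT"[1 if u < 0.3 else 2 if u < 0.6 else 0 if u < 0.8 else 3])
            i += 1
    return out[:n]


def simulate_genome(
    config: SimConfig,
) -> tuple[GenomeAssembly, FeatureIntervals, pd.DataFrame]:
    """Background genome with promoter-planted GC skew and CpG islands.

    Skew of the configured amplitude is planted downstream of every
    LUAT-class promoter (reading in the gene's orientation) with the
    mirrored deficit upstream; CpG-dense blocks are centered on promoters
    with per-class probabilities.  Returns the assembly, the planted-island
    track and a table of planted skew regions.
    """
    gcf = config.genome
    rng = _rng(config, 2)
    loci = plan_loci(config)

    chrom_arrays = {
        f"chr{i + 1}": _random_bases(rng, gcf.chrom_length, gcf.gc)
        for i in range(gcf.n_chroms)
    }

    skew_rows = []
    if gcf.skew_amplitude != 0:
        for loc in loci:
            if loc.gene_class != "luat_associated":
                continue
            arr = chrom_arrays[loc.chrom]
            ext = gcf.skew_extent
            sense = 1 if loc.strand == "+" else -1
            if loc.strand == "+":
                down = (loc.tss, loc.tss + ext)
                up = (loc.tss - ext, loc.tss)
            else:
                down = (loc.tss - ext + 1, loc.tss + 1)
                up = (loc.tss + 1, loc.tss + ext + 1)
            for (a, b), oriented_skew in ((down, gcf.skew_amplitude), (up, -gcf.skew_amplitude)):
                if a < 0 or b > gcf.chrom_length:
                    raise ValueError(f"planted skew region exceeds {loc.chrom}")
                genomic_skew = oriented_skew * sense
                arr[a:b] = _random_bases(rng, b - a, gcf.gc, genomic_skew)
                skew_rows.append(
                    {"gene_id": loc.gene_id, "chrom": loc.chrom, "start": a,
                     "end": b, "oriented_skew": oriented_skew}
                )

    # background CpG depletion: methyl-CpG deamination turns CpG into TpG,
    # which is what makes CpG islands stand out; planted skew regions are
    # exempt so their G/C balance stays at the configured amplitude.
    if gcf.cpg_depletion > 0:
        protected: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_arrays}
        for r in skew_rows:
            protected[r["chrom"]].append((r["start"], r["end"]))
        for chrom, arr in chrom_arrays.items():
            cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            if protected[chrom]:
                mask = np.zeros(len(arr), dtype=bool)
                for a, b in protected[chrom]:
                    mask[a:b] = True
                cg = cg[~mask[cg]]
            hit = cg[rng.random(cg.size) < gcf.cpg_depletion]
            # deamination is strand-symmetric (CpG is its own reverse
            # complement): half the events read C->T on the plus strand,
            # half G->A (the minus-strand C), keeping the global skew ~0
            on_plus = rng.random(hit.size) < 0.5
            arr[hit[on_plus]] = ord("T")
            arr[hit[~on_plus] + 1] = ord("A")

    island_rows = []
    for loc in loci:
        p = gcf.cpg_island_prob.get(loc.gene_class, 0.0)
        if rng.random() >= p:
            continue
        length = int(np.clip(_lognormal(rng, gcf.cpg_island_median_bp,
                                        gcf.cpg_island_sigma), 300, 4000))
        a = loc.tss - length // 2
        b = a + length
        if a < 0 or b > gcf.chrom_length:
            raise ValueError(f"planted CpG island exceeds {loc.chrom}")
        chrom_arrays[loc.chrom][a:b] = _cpg_block(rng, length)
        island_rows.append((loc.chrom, a, b))

    genome = GenomeAssembly(
        {c: arr.tobytes().decode("ascii") for c, arr in chrom_arrays.items()}
    )
    islands = FeatureIntervals("planted_cpg", island_rows)
    skew_table = pd.DataFrame(
        skew_rows, columns=["gene_id", "chrom", "start", "end", "oriented_skew"]
    )
    return genome, islands, skew_table


# ---------------------------------------------------------------------------
# annotation + truth

def simulate_annotation(
    config: SimConfig,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Transcript models plus the per-gene truth table.

    Truth columns: gene class, generative FPKM, planted LUAT interval and
    5' offset (LUAT-class genes only), LUAT FPKM and the first-intron
    retention fraction in effect.
    """
    loci = plan_loci(config)
    ecf = config.expression
    rng = _rng(config, 3)

    transcripts = []
    rows = []
    for loc in loci:
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{loc.gene_id}.t1",
                gene_id=loc.gene_id,
                chrom=loc.chrom,
                strand=loc.strand,
                exons=loc.exons,
                is_coding=True,
            )
        )
        fpkm = float(_lognormal(rng, ecf.gene_fpkm_median, ecf.gene_fpkm_sigma))
        row = {
            "gene_id": loc.gene_id,
            "transcript_id": f"{loc.gene_id}.t1",
            "gene_class": loc.gene_class,
            "chrom": loc.chrom,
            "strand": loc.strand,
            "tss": loc.tss,
            "fpkm": fpkm,
            "retention": ecf.intron1_retention,
            "luat_start": -1,
            "luat_end": -1,
            "luat_strand": "",
            "luat_offset": 0,
            "luat_fpkm": 0.0,
        }
        if loc.gene_class == "luat_associated":
            length = int(np.clip(_lognormal(rng, ecf.luat_length_median,
                                            ecf.luat_length_sigma),
                                 *ecf.luat_length_range))
            offset = -int(np.clip(rng.exponential(ecf.luat_offset_mean),
                                  0, ecf.luat_offset_max))
            luat_fpkm = float(np.clip(_lognormal(rng, ecf.luat_fpkm_median,
                                                 ecf.luat_fpkm_sigma),
                                      ecf.luat_fpkm_min, None))
            if loc.strand == "+":
                five_p = loc.tss + offset
                interval = (five_p - length + 1, five_p + 1)
                luat_strand = "-"
            else:
                five_p = loc.tss - offset
                interval = (five_p, five_p + length)
                luat_strand = "+"
            row.update(
                luat_start=interval[0], luat_end=interval[1],
                luat_strand=luat_strand, luat_offset=offset, luat_fpkm=luat_fpkm,
            )
        rows.append(row)
    truth = pd.DataFrame(rows)
    return transcripts, truth


# ---------------------------------------------------------------------------
# reads

def _place_fragments(rng, template: Sequence[tuple[int, int]], n: int, frag_len: int):
    """Uniformly sample ``n`` fragment intervals over a spliced template.

    The template is a list of genomic intervals; a fragment starts at a
    uniform template position and is clipped at its interval's end (no
    junction-split fragments are emitted).
    """
    sizes = np.array([e - s for s, e in template], dtype=np.int64)
    total = sizes.sum()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    pos = rng.integers(0, total, size=n)
    idx = np.searchsorted(offsets, pos, side="right") - 1
    out = []
    for p, i in zip(pos, idx):
        s = template[i][0] + (p - offsets[i])
        e = min(s + frag_len, template[i][1])
        if e > s:
            out.append((int(s), int(e)))
    return out


def simulate_reads(
    annotation: Sequence[TranscriptModel],
    truth: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> StrandedReadSet:
    """Stranded fragment set: genes, planted LUATs and background noise.

    Per transcript the fragment count is Poisson with mean
    ``FPKM * exonic_kb * library_Mfrags``; fragments are placed uniformly
    on the mature transcript except for the configured unspliced
    (pre-mRNA) fraction and the extra intron-1-retaining fraction.  LUAT
    fragments are drawn antisense over the planted interval; background
    fragments fall uniformly on both strands genome-wide.
    """
    ecf = config.expression
    if ecf.library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = (
        np.random.default_rng([int(seed) % (2**31), 4])
        if seed is not None
        else _rng(config, 4)
    )
    lib_m = ecf.library_size / 1e6
    frag_len = ecf.fragment_length
    by_id = {t.transcript_id: t for t in annotation}

    records: list[tuple] = []
    for row in truth.itertuples(index=False):
        t = by_id[row.transcript_id]
        n = rng.poisson(row.fpkm * t.exonic_length / 1000 * lib_m)
        if n > 0:
            f_pre = ecf.premrna_fraction
            f_ret = row.retention
            n_pre, n_ret = rng.multinomial(n, [f_pre, f_ret, 1 - f_pre - f_ret])[:2]
            n_mat = n - n_pre - n_ret
            exons5 = t.exons_5to3()
            if n_mat:
                for s, e in _place_fragments(rng, t.exons, n_mat, frag_len):
                    records.append((t.chrom, s, e, t.strand))
            if n_pre:
                for s, e in _place_fragments(rng, [t.span], n_pre, frag_len):
                    records.append((t.chrom, s, e, t.strand))
            if n_ret:
                # spliced everywhere except intron 1
                i1 = t.first_intron
                tmpl = sorted(list(t.exons) + [i1])
                for s, e in _place_fragments(rng, tmpl, n_ret, frag_len):
                    records.append((t.chrom, s, e, t.strand))
        if row.luat_start >= 0 and row.luat_fpkm > 0:
            length = row.luat_end - row.luat_start
            n_luat = rng.poisson(row.luat_fpkm * length / 1000 * lib_m)
            if n_luat:
                for s, e in _place_fragments(
                    rng, [(row.luat_start, row.luat_end)], n_luat, frag_len
                ):
                    records.append((row.chrom, s, e, row.luat_strand))

    # background noise, both strands, uniform genome-wide
    for i in range(config.genome.n_chroms):
        chrom = f"chr{i + 1}"
        L = config.genome.chrom_length
        for strand in "+-":
            n_bg = rng.poisson(ecf.background_per_kb * L / 1000)
            if n_bg:
                starts = rng.integers(0, L - frag_len, size=n_bg)
                for s in starts:
                    records.append((chrom, int(s), int(s) + frag_len, strand))

    return StrandedReadSet.from_records(records, label="simulated")


# ---------------------------------------------------------------------------
# multi-tissue expression

def simulate_multitissue(config: SimConfig):
    """Multi-tissue FPKM table for LUAT/gene pairs with controlled
    correlation and planted tissue-specific genes.

    Gene vectors are log-normal across conditions; a configured fraction
    is boosted ``specific_fold``-fold in one tissue.  Each paired LUAT
    vector is built as ``rho * standardized(gene) + sqrt(1 - rho^2) *
    noise`` (rescaled, floored at 0), so the linear Pearson correlation
    with its gene is ``rho`` in expectation.
    """
    tcf = config.tissues
    if tcf.n_conditions < 4:
        raise ValueError("need >= 4 conditions")
    rho = tcf.pair_correlation
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = _rng(config, 5)

    conditions = [f"tissue{i + 1:02d}" for i in range(tcf.n_conditions)]
    rows = {}
    truth_rows = []
    for i in range(tcf.n_pairs):
        gid, lid = f"g{i:04d}", f"luat_g{i:04d}"
        base = _lognormal(rng, tcf.base_fpkm_median, tcf.base_fpkm_sigma,
                          size=tcf.n_conditions)
        specific_in = ""
        if rng.random() < tcf.specific_fraction:
            k = int(rng.integers(tcf.n_conditions))
            base[k] *= tcf.specific_fold
            specific_in = conditions[k]
        g = base
        gs = (g - g.mean()) / (g.std() + 1e-12)
        noise = rng.normal(size=tcf.n_conditions)
        mix = rho * gs + np.sqrt(max(0.0, 1 - rho**2)) * noise
        luat = np.maximum(0.0, 3.0 + 1.0 * mix) * 1.0
        rows[gid] = g
        rows[lid] = luat
        truth_rows.append(
            {"gene_id": gid, "luat_id": lid, "rho": rho, "specific_in": specific_in}
        )

    from .expranalysis import ExpressionTable

    values = pd.DataFrame.from_dict(rows, orient="index", columns=conditions)
    values.index.name = "entity_id"
    kinds = {e: ("luat" if e.startswith("luat_") else "gene") for e in values.index}
    return ExpressionTable(values, kinds), pd.DataFrame(truth_rows)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genome, islands, skew table, annotation, truth,
    reads — the full single-condition dataset."""
    genome, islands, skew = simulate_genome(config)
    annotation, truth = simulate_annotation(config)
    reads = simulate_reads(annotation, truth, config)
    return {
        "genome": genome,
        "cpg_islands": islands,
        "skew_table": skew,
        "annotation": annotation,
        "truth": truth,
        "reads": reads,
    }
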