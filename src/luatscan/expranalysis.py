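"""Expression-level statistics.

Tissue-specificity scores, LUAT/gene pair correlation across conditions,
co-regulation contingency testing, the splicing index (exonic vs intronic
FPKM, a readout of immature transcription), and first-intron read
density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import quantify_fpkm
from .types import StrandedReadSet, TranscriptModel

__all__ = [
    "ExpressionTable",
    "TissueSpecificityResult",
    "SplicingIndexResult",
    "tissue_specificity",
    "pair_correlation",
    "coregulation_test",
    "splicing_index",
    "splicing_index_from_reads",
    "first_intron_density",
]


class ExpressionTable:
    """entity x condition FPKM matrix with an entity-kind annotation."""

    def __init__(self, values: pd.DataFrame, kinds: Mapping[str, str] | None = None):
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")
        self.values = values.astype(float)
        self.kinds = dict(kinds or {})

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        kinds = {}
        if "kind" in frame.columns:
            kinds = dict(zip(frame["entity_id"], frame["kind"]))
            frame = frame.drop(columns=["kind"])
        frame = frame.set_index("entity_id")
        return cls(frame, kinds)

    def to_tsv(self, path) -> None:
        frame = self.values.copy()
        if self.kinds:
            frame.insert(0, "kind", [self.kinds.get(e, "gene") for e in frame.index])
        frame.rename_axis("entity_id").reset_index().to_csv(path, sep="\t", index=False)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    def vector(self, entity: str) -> np.ndarray:
        if entity not in self.values.index:
            raise KeyError(f"unknown entity {entity!r}")
        return self.values.loc[entity].to_numpy(dtype=float)


@dataclass
class TissueSpecificityResult:
    entity_id: str
    condition: str
    ts: float  # NaN when IQR == 0
    specific: bool


@dataclass
class SplicingIndexResult:
    transcript_id: str
    si_5prime: float
    si_middle: float
    exon5_fpkm: float
    intron1_fpkm: float
    middle_exon_fpkm: float
    middle_intron_fpkm: float


def tissue_specificity(
    expr: ExpressionTable, entity: str, condition: str
) -> TissueSpecificityResult:
    """TS = (e - Q3) / (Q3 - Q1) over the entity's condition vector.

    Quartiles use linear interpolation (type 7).  TS > 1 flags the entity
    as specific to the condition; a zero interquartile range leaves TS
    undefined (NaN) and the entity non-specific.
    """
    vec = expr.vector(entity)
    if vec.size < 4:
        raise ValueError("tissue specificity needs >= 4 conditions")
    if condition not in expr.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    e = float(expr.values.loc[entity, condition])
    q1, q3 = np.percentile(vec, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return TissueSpecificityResult(entity, condition, float("nan"), False)
    ts = float((e - q3) / iqr)
    return TissueSpecificityResult(entity, condition, ts, ts > 1)


def pair_correlation(
    expr: ExpressionTable, pairs: Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, int]:
    """Pearson r per (entity_a, entity_b) pair across conditions.

    Pairs where either member has zero variance are excluded; the count of
    exclusions is returned alongside the result table.
    """
    rows = []
    n_excluded = 0
    for a, b in pairs:
        va, vb = expr.vector(a), expr.vector(b)
        if np.std(va) == 0 or np.std(vb) == 0:
            n_excluded += 1
            continue
        r = float(stats.pearsonr(va, vb).statistic)
        rows.append({"id_a": a, "id_b": b, "pearson_r": r})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pearson_r"]), n_excluded


def coregulation_test(
    expr_cond1: Mapping[str, float],
    expr_cond2: Mapping[str, float],
    pairs: Sequence[tuple[str, str]],
    fold: float = 2.0,
    pseudo: float = 0.01,
    drop_discordant: bool = False,
) -> tuple[np.ndarray, float, float, int]:
    """Chi-square association between LUAT and gene expression changes.

    Each pair member is "changed" when |log2((e1 + pseudo) / (e2 +
    pseudo))| >= log2(fold).  The 2x2 table crosses (LUAT changed?, gene
    changed?).  Pairs where both members changed in opposite directions
    are counted (``n_discordant``) and, with ``drop_discordant``, removed
    from the table so the both-changed cell holds only same-direction
    (co-regulated) pairs; the default keeps them, which preserves the
    test's type-I calibration under independence.  Returns (table, chi2,
    p, n_discordant); chi-square is computed without continuity
    correction.
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    log_fold = np.log2(fold)
    table = np.zeros((2, 2), dtype=int)
    n_discordant = 0
    for luat_id, gene_id in pairs:
        l_ratio = np.log2((expr_cond1[luat_id] + pseudo) / (expr_cond2[luat_id] + pseudo))
        g_ratio = np.log2((expr_cond1[gene_id] + pseudo) / (expr_cond2[gene_id] + pseudo))
        l_chg = abs(l_ratio) >= log_fold
        g_chg = abs(g_ratio) >= log_fold
        if l_chg and g_chg and np.sign(l_ratio) != np.sign(g_ratio):
            n_discordant += 1
            if drop_discordant:
                continue
        table[0 if l_chg else 1, 0 if g_chg else 1] += 1
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (a margin is empty)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return table, float(chi2), float(p), n_discordant


def splicing_index(
    exon_fpkm: Sequence[float],
    intron_fpkm: Sequence[float],
    transcript_id: str = "",
    transcript_fpkm: float | None = None,
    pseudo: float = 0.01,
    both_flanks: bool = True,
) -> SplicingIndexResult:
    """Splicing indices from per-feature FPKMs (5'->3' transcript order).

    ``si_5prime = log2(mean(exon1, exon2) / intron1)`` and ``si_middle``
    pairs the central exon (mean of the two central exons for an even
    count) with the mean of its flanking introns (or the 5' flank alone
    when ``both_flanks`` is false).  Every feature receives ``pseudo``
    before forming ratios.  Requires >= 4 exons and, when supplied, a
    transcript FPKM above 0.1.
    """
    exons = np.asarray(exon_fpkm, dtype=float) + pseudo
    introns = np.asarray(intron_fpkm, dtype=float) + pseudo
    n = exons.size
    if n < 4:
        raise ValueError("splicing index requires >= 4 exons")
    if introns.size != n - 1:
        raise ValueError("expected one intron fewer than exons")
    if transcript_fpkm is not None and transcript_fpkm <= 0.1:
        raise ValueError("transcript FPKM must exceed 0.1")

    exon5 = float(exons[:2].mean())
    intron1 = float(introns[0])
    si5 = float(np.log2(exon5 / intron1))

    if n % 2 == 1:
        mid = n // 2
        mid_exon = float(exons[mid])
        flank_in = (introns[mid - 1], introns[mid])
    else:
        mid = n // 2 - 1
        mid_exon = float(exons[mid : mid + 2].mean())
        flank_in = (introns[mid - 1], introns[mid + 1])
    mid_intron = float(np.mean(flank_in) if both_flanks else flank_in[0])
    si_mid = float(np.log2(mid_exon / mid_intron))
    return SplicingIndexResult(
        transcript_id, si5, si_mid, exon5, intron1, mid_exon, mid_intron
    )


def splicing_index_from_reads(
    reads: StrandedReadSet,
    transcript: TranscriptModel,
    library_size: int,
    pseudo: float = 0.01,
    both_flanks: bool = True,
) -> SplicingIndexResult:
    """Quantify per-exon / per-intron FPKMs for a transcript and compute
    its splicing indices.  Skips (raises) on <4 exons or FPKM <= 0.1."""
    if transcript.n_exons < 4:
        raise ValueError(f"{transcript.transcript_id}: needs >= 4 exons")
    tx_fpkm = quantify_fpkm(
        reads, transcript.chrom, transcript.strand, transcript.exons, library_size
    )
    if tx_fpkm <= 0.1:
        raise ValueError(f"{transcript.transcript_id}: FPKM {tx_fpkm:.3g} <= 0.1")
    exon_f = [
        quantify_fpkm(reads, transcript.chrom, transcript.strand, [ex], library_size)
        for ex in transcript.exons_5to3()
    ]
    intron_f = [
        quantify_fpkm(reads, transcript.chrom, transcript.strand, [iv], library_size)
        for iv in transcript.introns
    ]
    return splicing_index(
        exon_f, intron_f, transcript.transcript_id, tx_fpkm, pseudo, both_flanks
    )


def first_intron_density(
    reads: StrandedReadSet, transcript: TranscriptModel, library_size: int | None = None
) -> float:
    """Same-strand fragments overlapping the strand-aware first intron,
    per bp of intron."""
    s, e = transcript.first_intron  # raises on intron-less transcripts
    sub = reads.subset(transcript.chrom, transcript.strand)
    if sub.empty:
        return 0.0
    count = int(((sub["start"] < e) & (sub["end"] > s)).sum())
    return count / (e - s)
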