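"""Promoter sequence features.

GC content and GC skew metagene profiles, CpG-island detection with the
classical Gardiner-Garden & Frommer thresholds, position-weight-matrix
(TATA box) scoring, and 5'-splice-site accumulation curves.  All
orientation-sensitive features are computed on the gene's sense strand:
minus-strand promoters use the reverse complement, so a positive
downstream GC skew reads the same way for every gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal import MetaProfile
from .types import FeatureIntervals, GenomeAssembly, TranscriptModel

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> index for PWM rows (A,C,G,T); N handled separately
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

__all__ = [
    "PWM",
    "reverse_complement",
    "gc_content_profile",
    "gc_skew",
    "gc_skew_profile",
    "detect_cpg_islands",
    "promoter_cpg_summary",
    "pwm_max_score",
    "splice_site_accumulation",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Log-odds position weight matrix (bits) over A,C,G,T columns."""

    motif_id: str
    matrix: np.ndarray  # (4, L) log2-odds
    background: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM matrix must be 4 x L with L >= 4")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudo: float = 0.01,
    ) -> "PWM":
        """Build a log2-odds PWM from a count matrix with a pseudo-count."""
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = (counts + pseudo) / (counts + pseudo).sum(axis=0, keepdims=True)
        return cls(motif_id, np.log2(probs / bg[:, None]), bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def scan(self, seq: str) -> np.ndarray:
        """Score every position of ``seq``; N scores as the column minimum.

        Returns an array of length ``len(seq) - L + 1`` (empty when the
        sequence is shorter than the motif).
        """
        L = self.length
        n = len(seq) - L + 1
        if n <= 0:
            return np.empty(0)
        col_min = self.matrix.min(axis=0)
        # per-base score lookup including N -> column minimum
        lookup = np.vstack([self.matrix, col_min[None, :]])  # (5, L)
        idx = np.fromiter(
            (_BASE_IDX.get(b, 4) for b in seq), dtype=np.int8, count=len(seq)
        )
        scores = np.zeros(n)
        for j in range(L):
            scores += lookup[idx[j : j + n], j]
        return scores


# ---------------------------------------------------------------------------
# GC content / skew

def _oriented_window(genome: GenomeAssembly, t: TranscriptModel, flank: int) -> str | None:
    """Sense-strand sequence of the 2*flank window around the TSS (the TSS
    base starts the downstream half), or None at chromosome edges."""
    if t.strand == "+":
        w0, w1 = t.tss - flank, t.tss + flank
    else:
        w0, w1 = t.tss - flank + 1, t.tss + flank + 1
    if w0 < 0 or w1 > genome.length(t.chrom):
        return None
    seq = genome.sequence(t.chrom, w0, w1)
    return seq if t.strand == "+" else reverse_complement(seq)


def gc_content_profile(
    genome: GenomeAssembly,
    anchors: Sequence[TranscriptModel],
    flank: int = 5000,
    bin_bp: int = 100,
) -> MetaProfile:
    """Mean per-bin GC fraction around TSSs (oriented; N excluded)."""
    if flank % bin_bp != 0:
        raise ValueError("flank must be divisible by bin_bp")
    n_bins = 2 * flank // bin_bp
    totals = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    used = 0
    for t in anchors:
        seq = _oriented_window(genome, t, flank)
        if seq is None:
            continue
        used += 1
        for b in range(n_bins):
            chunk = seq[b * bin_bp : (b + 1) * bin_bp]
            denom = len(chunk) - chunk.count("N")
            if denom == 0:
                continue
            totals[b] += (chunk.count("G") + chunk.count("C")) / denom
            counts[b] += 1
    if used == 0:
        raise ValueError("no usable anchors")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    positions = np.arange(-flank, flank, bin_bp) + bin_bp // 2
    return MetaProfile(positions.astype(float), values, used)


def gc_skew(seq: str) -> float:
    """(#G - #C) / (#G + #C); NaN when the window holds no G or C."""
    if not seq:
        raise ValueError("empty sequence")
    g = seq.count("G")
    c = seq.count("C")
    if g + c == 0:
        return float("nan")
    return (g - c) / (g + c)


def gc_skew_profile(
    genome: GenomeAssembly,
    anchors: Sequence[TranscriptModel],
    flank: int = 5000,
    bin_bp: int = 100,
) -> MetaProfile:
    """Mean per-bin GC skew around TSSs in the gene's reading orientation."""
    if flank % bin_bp != 0:
        raise ValueError("flank must be divisible by bin_bp")
    n_bins = 2 * flank // bin_bp
    acc = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    used = 0
    for t in anchors:
        seq = _oriented_window(genome, t, flank)
        if seq is None:
            continue
        used += 1
        for b in range(n_bins):
            sk = gc_skew(seq[b * bin_bp : (b + 1) * bin_bp])
            if not np.isnan(sk):
                acc[b] += sk
                counts[b] += 1
    if used == 0:
        raise ValueError("no usable anchors")
    values = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    positions = np.arange(-flank, flank, bin_bp) + bin_bp // 2
    return MetaProfile(positions.astype(float), values, used)


# ---------------------------------------------------------------------------
# CpG islands

def _cpg_stats(gc_cum, g_cum, c_cum, cpg_cum, s: int, e: int) -> tuple[float, float]:
    """(GC fraction, observed/expected CpG) of [s, e) from prefix sums."""
    L = e - s
    gc = (gc_cum[e] - gc_cum[s]) / L
    n_c = c_cum[e] - c_cum[s]
    n_g = g_cum[e] - g_cum[s]
    n_cpg = cpg_cum[min(e - 1, len(cpg_cum) - 1)] - cpg_cum[s]
    oe = (n_cpg * L) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def detect_cpg_islands(
    genome: GenomeAssembly,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
) -> FeatureIntervals:
    """Sliding-window CpG-island caller (Gardiner-Garden & Frommer rules).

    Windows of ``window`` bp passing both thresholds (GC >= ``min_gc``,
    observed/expected CpG >= ``min_oe``) are merged greedily: a growing
    island absorbs the next passing window only while the union still
    passes both thresholds, so every reported interval re-satisfies the
    criteria and is >= ``min_len`` bp.  Intended for synthetic genomes;
    supply a curated track as BED for real assemblies.
    """
    islands = []
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom, 0, genome.length(chrom))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_g = arr == ord("G")
        is_c = arr == ord("C")
        is_cpg = is_c[:-1] & is_g[1:] if len(arr) > 1 else np.zeros(0, bool)
        g_cum = np.concatenate([[0], np.cumsum(is_g)])
        c_cum = np.concatenate([[0], np.cumsum(is_c)])
        gc_cum = np.concatenate([[0], np.cumsum(is_g | is_c)])
        cpg_cum = np.concatenate([[0], np.cumsum(is_cpg)])

        def ok(s: int, e: int) -> bool:
            gc, oe = _cpg_stats(gc_cum, g_cum, c_cum, cpg_cum, s, e)
            return gc >= min_gc and oe >= min_oe

        n = len(arr)
        if n < window:
            continue
        # vectorized window test at every start
        L = window
        gcf = (gc_cum[L:] - gc_cum[:-L]) / L
        ng = (g_cum[L:] - g_cum[:-L]).astype(float)
        nc = (c_cum[L:] - c_cum[:-L]).astype(float)
        # CpG dimers fully inside [s, s+L)
        ncpg = (cpg_cum[L - 1 :] - cpg_cum[: -(L - 1)]).astype(float)[: len(gcf)]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((ng > 0) & (nc > 0), ncpg * L / (ng * nc), 0.0)
        passing = np.flatnonzero((gcf >= min_gc) & (oe >= min_oe))

        i = 0
        while i < len(passing):
            s = int(passing[i])
            e = s + window
            j = i + 1
            while j < len(passing):
                ws = int(passing[j])
                if ws > e:  # disjoint and non-adjacent: close the island
                    break
                cand_e = max(e, ws + window)
                if ok(s, cand_e):
                    e = cand_e
                    j += 1
                else:
                    break
            if e - s >= min_len and ok(s, e):
                islands.append((chrom, s, e))
            # restart after the island (keeps output disjoint)
            while j < len(passing) and passing[j] < e:
                j += 1
            i = j
    return FeatureIntervals("cpg_island", islands)


def promoter_cpg_summary(
    islands: FeatureIntervals,
    genes: Sequence[TranscriptModel],
    size_window: int = 1000,
    cover_window: int = 500,
    clip: bool = False,
) -> dict[str, tuple[bool, int]]:
    """Per-gene CpG-island coverage flag and total island bp near the TSS.

    ``covered`` is true when >=1 island overlaps ``[TSS - cover_window,
    TSS + cover_window)``; ``total_island_bp`` sums the lengths of islands
    overlapping ``[TSS - size_window, TSS + size_window)`` (full island
    length by default; set ``clip`` to count only the overlapping part).
    """
    merged = islands.merged()
    out: dict[str, tuple[bool, int]] = {}
    for t in genes:
        cov_hits = merged.overlapping(t.chrom, t.tss - cover_window, t.tss + cover_window)
        sz_lo, sz_hi = t.tss - size_window, t.tss + size_window
        size_hits = merged.overlapping(t.chrom, sz_lo, sz_hi)
        if clip:
            total = int(
                sum(min(e, sz_hi) - max(s, sz_lo) for s, e in size_hits)
            )
        else:
            total = int(sum(e - s for s, e in size_hits))
        out[t.transcript_id] = (len(cov_hits) > 0, total)
    return out


# ---------------------------------------------------------------------------
# PWM scanning

def pwm_max_score(
    genome: GenomeAssembly,
    gene: TranscriptModel,
    pwm: PWM,
    window: int = 500,
) -> float:
    """Maximum PWM log-odds score in the sense-strand ``window`` bp
    centered on the TSS; truncated (with a warning) at chromosome edges."""
    if window < pwm.length:
        raise ValueError("window shorter than motif")
    half = window // 2
    w0, w1 = gene.tss - half, gene.tss + (window - half)
    if w0 < 0 or w1 > genome.length(gene.chrom):
        logger.warning("PWM window for %s truncated at chromosome edge", gene.transcript_id)
        w0, w1 = max(0, w0), min(genome.length(gene.chrom), w1)
    seq = genome.sequence(gene.chrom, w0, w1)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    scores = pwm.scan(seq)
    if scores.size == 0:
        return float(pwm.matrix.min(axis=0).sum())
    return float(scores.max())


def splice_site_accumulation(
    genome: GenomeAssembly,
    genes: Sequence[TranscriptModel],
    pwm: PWM,
    span: int = 500,
    threshold: float = 0.0,
) -> MetaProfile:
    """Cumulative fraction of genes with >=1 motif hit within the first x
    downstream nucleotides (sense strand), for x = 1..span.

    A hit starting at the s-th downstream base (1-based) registers once x
    reaches ``s + L - 1`` — the traversal has then read the full motif.
    """
    if span <= pwm.length:
        raise ValueError("span must exceed motif length")
    first_covered = []
    n = len(genes)
    if n == 0:
        raise ValueError("no genes")
    for t in genes:
        if t.strand == "+":
            seq = genome.sequence(t.chrom, t.tss, t.tss + span)
        else:
            seq = reverse_complement(genome.sequence(t.chrom, t.tss - span + 1, t.tss + 1))
        scores = pwm.scan(seq)
        hits = np.flatnonzero(scores >= threshold)
        if hits.size:
            first_covered.append(int(hits[0]) + pwm.length)  # 1-based end of first hit
    xs = np.arange(1, span + 1)
    counts = np.zeros(span)
    for fc in first_covered:
        if fc <= span:
            counts[fc - 1 :] += 1
    return MetaProfile(xs.astype(float), counts / n, n)
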