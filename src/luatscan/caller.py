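"""Empirical-null calibration and LUAT calling.

A promoter is called LUAT-positive when the summed antisense bin coverage
of its upstream 5 kb exceeds a threshold derived from the same statistic
computed on random intergenic regions: the threshold is the order
statistic that leaves at most a fraction ``alpha`` (default 0.005) of the
null scores strictly above it.  Null regions run through the identical
binning/transform code path as candidate promoters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal import Anchor, StrandedCoverage, antisense_score, binned_promoter_signal
from .types import GenomeAssembly, TranscriptModel

__all__ = [
    "NullDistribution",
    "LuatCall",
    "sample_intergenic_regions",
    "null_distribution_from_regions",
    "empirical_threshold",
    "candidate_antisense_scores",
    "call_luats",
]


@dataclass
class NullDistribution:
    """Antisense bin-sum scores of random intergenic regions."""

    scores: np.ndarray
    bin_bp: int
    flank: int
    transform: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValueError("empty null distribution")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("null scores must be finite and >= 0")

    @property
    def m(self) -> int:
        return int(self.scores.size)


@dataclass
class LuatCall:
    """Per-candidate antisense score and call, plus assembled-LUAT fields."""

    gene_id: str
    antisense_score: float
    called: bool
    threshold_used: float
    luat_interval: tuple[str, int, int, str] | None = None
    luat_offset_bp: int | None = None
    luat_fpkm: float | None = None


def sample_intergenic_regions(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeAssembly | Mapping[str, int],
    m: int = 10000,
    length: int = 5000,
    buffer: int = 1000,
    seed: int = 0,
) -> list[Anchor]:
    """Sample ``m`` intergenic regions of exactly ``length`` bp.

    Start positions are drawn uniformly from all positions whose
    ``[start, start + length)`` window stays >= ``buffer`` bp away from
    every transcript span; each region gets a random pseudo-TSS
    orientation.  The returned anchors mark the region's 5' edge so the
    downstream ``length`` window reproduces the candidate upstream-window
    geometry.  Deterministic given ``seed``.
    """
    lengths = genome.lengths if isinstance(genome, GenomeAssembly) else dict(genome)

    # allowed start intervals per chromosome: complement of (span +/- buffer)
    valid: list[tuple[str, int, int]] = []  # (chrom, first_start, last_start_excl)
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for t in transcripts:
        if t.chrom in spans:
            spans[t.chrom].append((max(0, t.start - buffer), t.end + buffer))
    for chrom, L in lengths.items():
        merged: list[list[int]] = []
        for s, e in sorted(spans[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        gaps = []
        for s, e in merged:
            gaps.append((cursor, s))
            cursor = max(cursor, e)
        gaps.append((cursor, L))
        for g0, g1 in gaps:
            if g1 - g0 >= length:
                valid.append((chrom, g0, g1 - length + 1))

    total = sum(b - a for _, a, b in valid)
    needed = m * length
    available_bp = sum(b - a for _, a, b in valid) + (length - 1) * len(valid)
    if total <= 0 or available_bp < needed:
        raise ValueError(
            f"insufficient intergenic space: {available_bp} bp available, "
            f"{needed} bp required (m={m} x length={length})"
        )

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, total, size=m)
    strands = rng.choice(["+", "-"], size=m)
    bounds = np.cumsum([b - a for _, a, b in valid])
    anchors = []
    for i, (p, st) in enumerate(zip(picks, strands)):
        j = int(np.searchsorted(bounds, p, side="right"))
        chrom, a0, _ = valid[j]
        start = int(a0 + p - (bounds[j - 1] if j else 0))
        # pseudo-TSS at the 5' edge of the region, reading downstream
        pos = start if st == "+" else start + length - 1
        anchors.append(Anchor(f"null_{i}", chrom, pos, str(st)))
    return anchors


def null_distribution_from_regions(
    cov: StrandedCoverage,
    regions: Sequence[Anchor],
    length: int = 5000,
    bin_bp: int = 100,
    transform: str = "log2p1",
) -> NullDistribution:
    """Antisense bin-sum scores for sampled intergenic regions.

    Each region carries a pseudo-TSS orientation (its anchor marks the 5'
    edge, reading downstream over ``length`` bp).  The score is the sum
    over the region's ``length / bin_bp`` bins of the transformed coverage
    on the strand opposite the pseudo-orientation — the same binning,
    transform and summation used for candidate promoters, applied to a
    region with the upstream-window geometry.
    """
    from .signal import _apply_transform, _bin_sums
    from .types import opposite_strand

    if length % bin_bp != 0:
        raise ValueError("length must be divisible by bin_bp")
    n_bins = length // bin_bp
    scores = np.empty(len(regions), dtype=float)
    for i, a in enumerate(regions):
        start = a.position if a.strand == "+" else a.position - length + 1
        vec = cov.data.get((a.chrom, opposite_strand(a.strand)))
        row = _apply_transform(_bin_sums(vec, start, n_bins, bin_bp), transform)
        scores[i] = antisense_score(row, n_bins)
    return NullDistribution(scores=scores, bin_bp=bin_bp, flank=length, transform=transform)


def empirical_threshold(null: NullDistribution, alpha: float = 0.005) -> float:
    """Calling threshold from the null score distribution.

    Returns the k-th smallest null score with ``k = ceil((1 - alpha) * M)``
    (computed as ``M - floor(alpha * M)``, which is the same order statistic
    but numerically robust), guaranteeing that the fraction of null scores
    strictly above the threshold is at most ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    scores = np.sort(null.scores)
    k = null.m - math.floor(alpha * null.m)
    k = min(max(k, 1), null.m)
    return float(scores[k - 1])


def candidate_antisense_scores(
    cov: StrandedCoverage,
    candidates: Sequence[TranscriptModel],
    flank: int = 5000,
    bin_bp: int = 100,
    transform: str = "log2p1",
    upstream_bins: int | None = None,
) -> dict[str, float]:
    """Upstream antisense bin-sum score per candidate gene."""
    if upstream_bins is None:
        upstream_bins = flank // bin_bp
    _, anti = binned_promoter_signal(cov, candidates, flank, bin_bp, transform)
    id_to_gene = {t.transcript_id: t.gene_id for t in candidates}
    return {
        id_to_gene[rid]: float(antisense_score(row, upstream_bins))
        for rid, row in zip(anti.region_ids, anti.values)
    }


def call_luats(
    candidates: Sequence[TranscriptModel],
    antisense_scores: Mapping[str, float],
    threshold: float,
) -> list[LuatCall]:
    """Call candidates whose antisense score strictly exceeds the threshold."""
    calls = []
    for t in candidates:
        if t.gene_id not in antisense_scores:
            raise ValueError(f"no antisense score for candidate gene {t.gene_id!r}")
        score = float(antisense_scores[t.gene_id])
        calls.append(
            LuatCall(
                gene_id=t.gene_id,
                antisense_score=score,
                called=score > threshold,
                threshold_used=float(threshold),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[LuatCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        iv = c.luat_interval
        rows.append(
            {
                "gene_id": c.gene_id,
                "antisense_score": c.antisense_score,
                "threshold": c.threshold_used,
                "called": c.called,
                "luat_chrom": iv[0] if iv else "",
                "luat_start": iv[1] if iv else -1,
                "luat_end": iv[2] if iv else -1,
                "luat_strand": iv[3] if iv else "",
                "luat_offset_bp": c.luat_offset_bp if c.luat_offset_bp is not None else "",
                "luat_fpkm": c.luat_fpkm if c.luat_fpkm is not None else "",
            }
        )
    return pd.DataFrame(rows)
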