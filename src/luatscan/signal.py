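"""Stranded coverage, binned promoter matrices and metagene profiles.

The central object is a per-anchor matrix of binned coverage around TSSs:
100-bp bins over a +/-5 kb window by default, values transformed as
log2(coverage + 1), split into a sense and an antisense channel relative
to each anchor's strand.  Minus-strand anchors are orientation-flipped so
column 0 is always the most-upstream bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import (
    FeatureIntervals,
    GenomeAssembly,
    StrandedCoverage,
    StrandedReadSet,
    TranscriptModel,
    opposite_strand,
)

logger = logging.getLogger(__name__)

TRANSFORMS = ("raw", "log2p1")

__all__ = [
    "BinnedSignalMatrix",
    "MetaProfile",
    "Anchor",
    "coverage_from_reads",
    "binned_promoter_signal",
    "antisense_score",
    "meta_profile",
    "rescaled_region_profile",
    "feature_fraction_profile",
    "anchors_from_transcripts",
]


@dataclass
class Anchor:
    """An anchored, oriented window center (typically a TSS)."""

    region_id: str
    chrom: str
    position: int
    strand: str


@dataclass
class BinnedSignalMatrix:
    """Anchored regions x bins matrix of (transformed) binned coverage."""

    region_ids: list[str]
    values: np.ndarray  # (n_regions, n_bins)
    bin_bp: int
    flank: int
    transform: str
    channel: str  # "sense" | "antisense"

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row(self, region_id: str) -> np.ndarray:
        return self.values[self.region_ids.index(region_id)]


@dataclass
class MetaProfile:
    """Mean signal at each relative position across a set of regions."""

    positions: np.ndarray
    values: np.ndarray
    n_regions: int

    def __post_init__(self):
        if self.n_regions <= 0:
            raise ValueError("MetaProfile needs n_regions > 0")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("MetaProfile positions must be strictly increasing")


def anchors_from_transcripts(transcripts: Sequence[TranscriptModel]) -> list[Anchor]:
    return [Anchor(t.transcript_id, t.chrom, t.tss, t.strand) for t in transcripts]


def coverage_from_reads(
    reads: StrandedReadSet, genome: GenomeAssembly | dict
) -> StrandedCoverage:
    """Per-base fragment coverage, one vector per (chromosome, strand)."""
    lengths = genome.lengths if isinstance(genome, GenomeAssembly) else dict(genome)
    cov = StrandedCoverage(lengths=lengths)
    frame = reads.frame
    if frame.empty:
        return cov
    bad = ~frame["chrom"].isin(lengths)
    if bad.any():
        rec = frame[bad].iloc[0]
        raise ValueError(f"fragment on unknown chromosome: {tuple(rec)}")
    for (chrom, strand), grp in frame.groupby(["chrom", "strand"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts < 0).any() or (ends > lengths[chrom]).any():
            i = int(np.argmax((starts < 0) | (ends > lengths[chrom])))
            raise ValueError(
                f"fragment out of bounds on {chrom}: "
                f"[{starts[i]},{ends[i]}) vs length {lengths[chrom]}"
            )
        diff = np.zeros(lengths[chrom] + 1, dtype=np.int32)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        cov.data[(chrom, strand)] = np.cumsum(diff[:-1], dtype=np.int32)
    return cov


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "raw":
        return values.astype(float)
    if transform == "log2p1":
        return np.log2(values.astype(float) + 1.0)
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def _bin_sums(vec: np.ndarray | None, start: int, n_bins: int, bin_bp: int) -> np.ndarray:
    """Sums of per-base coverage over consecutive bins starting at ``start``."""
    if vec is None:
        return np.zeros(n_bins, dtype=float)
    window = vec[start : start + n_bins * bin_bp]
    return window.reshape(n_bins, bin_bp).sum(axis=1, dtype=np.int64).astype(float)


def binned_promoter_signal(
    cov: StrandedCoverage,
    anchors: Sequence[TranscriptModel | Anchor],
    flank: int = 5000,
    bin_bp: int = 100,
    transform: str = "log2p1",
) -> tuple[BinnedSignalMatrix, BinnedSignalMatrix]:
    """Binned coverage around each anchor, split into sense/antisense channels.

    The window holds ``2 * flank / bin_bp`` left-closed bins of ``bin_bp``
    with the anchor base in the first downstream bin: genomically
    ``[anchor - flank, anchor + flank)`` for plus-strand anchors and
    ``(anchor - flank, anchor + flank]`` for minus-strand ones, whose bin
    order is then reversed so column 0 is always the most-upstream bin and
    "sense" always means the anchor's own strand.  Anchors whose window
    leaves the chromosome are dropped with a warning.
    """
    if flank % bin_bp != 0:
        raise ValueError("flank must be divisible by bin_bp")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    n_bins = 2 * flank // bin_bp

    anchor_list = [
        a if isinstance(a, Anchor) else Anchor(a.transcript_id, a.chrom, a.tss, a.strand)
        for a in anchors
    ]
    ids: list[str] = []
    sense_rows: list[np.ndarray] = []
    anti_rows: list[np.ndarray] = []
    for a in anchor_list:
        if a.strand == "+":
            w0, w1 = a.position - flank, a.position + flank
        else:
            w0, w1 = a.position - flank + 1, a.position + flank + 1
        if w0 < 0 or w1 > cov.lengths.get(a.chrom, -1):
            logger.warning("anchor %s window exceeds chromosome; dropped", a.region_id)
            continue
        sense_vec = cov.data.get((a.chrom, a.strand))
        anti_vec = cov.data.get((a.chrom, opposite_strand(a.strand)))
        srow = _bin_sums(sense_vec, w0, n_bins, bin_bp)
        arow = _bin_sums(anti_vec, w0, n_bins, bin_bp)
        if a.strand == "-":
            srow = srow[::-1]
            arow = arow[::-1]
        ids.append(a.region_id)
        sense_rows.append(srow)
        anti_rows.append(arow)

    def _mat(rows, channel):
        values = np.vstack(rows) if rows else np.empty((0, n_bins))
        return BinnedSignalMatrix(
            region_ids=list(ids),
            values=_apply_transform(values, transform),
            bin_bp=bin_bp,
            flank=flank,
            transform=transform,
            channel=channel,
        )

    return _mat(sense_rows, "sense"), _mat(anti_rows, "antisense")


def antisense_score(row: np.ndarray, upstream_bins: int = 50) -> float:
    """Sum of the most-upstream ``upstream_bins`` bins of an antisense row."""
    row = np.asarray(row, dtype=float)
    if row.shape[0] < upstream_bins:
        raise ValueError(
            f"row has {row.shape[0]} bins but {upstream_bins} upstream bins requested"
        )
    return float(row[:upstream_bins].sum())


def meta_profile(
    cov: StrandedCoverage,
    anchors: Sequence[TranscriptModel | Anchor],
    flank: int = 5000,
    bin_bp: int = 100,
    channel: str = "sense",
    transform: str = "raw",
) -> MetaProfile:
    """Average (oriented) binned signal across anchors."""
    sense, anti = binned_promoter_signal(cov, anchors, flank, bin_bp, transform)
    mat = sense if channel == "sense" else anti
    if mat.values.shape[0] == 0:
        raise ValueError("no usable anchors for meta profile")
    positions = np.arange(-flank, flank, bin_bp) + bin_bp // 2
    return MetaProfile(
        positions=positions.astype(float),
        values=mat.values.mean(axis=0),
        n_regions=mat.values.shape[0],
    )


def rescaled_region_profile(
    cov: StrandedCoverage,
    regions: Sequence[tuple[str, int, int, str]],
    strand_channel: str = "sense",
    n_bins: int = 100,
) -> MetaProfile:
    """Average coverage over regions rescaled to a common ``n_bins`` axis.

    Each region (e.g. TSS to end of first intron) is split into ``n_bins``
    equal-fraction bins in its 5'->3' orientation; per-bin mean per-base
    coverage is averaged across regions.  Regions shorter than ``n_bins``
    bp are dropped with a warning.
    """
    rows = []
    for chrom, start, end, strand in regions:
        if end - start < n_bins:
            logger.warning("region (%s,%d,%d) shorter than %d bins; dropped",
                           chrom, start, end, n_bins)
            continue
        use_strand = strand if strand_channel == "sense" else opposite_strand(strand)
        vec = cov.data.get((chrom, use_strand))
        window = (
            np.zeros(end - start, dtype=float)
            if vec is None
            else vec[start:end].astype(float)
        )
        edges = np.linspace(0, end - start, n_bins + 1).round().astype(int)
        csum = np.concatenate([[0.0], np.cumsum(window)])
        sums = csum[edges[1:]] - csum[edges[:-1]]
        widths = np.diff(edges)
        row = sums / widths
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValueError("no usable regions for rescaled profile")
    return MetaProfile(
        positions=np.arange(n_bins, dtype=float),
        values=np.vstack(rows).mean(axis=0),
        n_regions=len(rows),
    )


def feature_fraction_profile(
    features: FeatureIntervals,
    anchors: Sequence[TranscriptModel | Anchor],
    flank: int = 5000,
    step: int = 10,
) -> MetaProfile:
    """Fraction of anchors covered by a feature at each relative position.

    At relative position ``d`` (oriented: positive = downstream of the
    anchor), the value is the fraction of anchors whose genomic base at
    that offset lies inside >=1 feature interval.  Values are in [0, 1].
    """
    anchor_list = [
        a if isinstance(a, Anchor) else Anchor(a.transcript_id, a.chrom, a.tss, a.strand)
        for a in anchors
    ]
    if not anchor_list:
        raise ValueError("no anchors")
    merged = features.merged()
    offsets = np.arange(-flank, flank + 1, step)
    hits = np.zeros(offsets.shape, dtype=float)
    for a in anchor_list:
        genomic = a.position + offsets if a.strand == "+" else a.position - offsets
        hits += merged.contains(a.chrom, genomic)
    return MetaProfile(
        positions=offsets.astype(float),
        values=hits / len(anchor_list),
        n_regions=len(anchor_list),
    )
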