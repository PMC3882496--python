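"""LUAT model assembly and quantification.

Transcribed fragments on the strand opposite a called gene are detected
as maximal coverage runs, then merged by a seed-and-extend rule: a
fragment whose 5' end lies within +/-1.5 kb of the gene TSS seeds the
model, which is extended in both directions while another fragment (>= 200
bp, same strand) lies at a gap of less than 800 bp.  The merged span is
quantified as a single-exon model in FPKM.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import StrandedCoverage, StrandedReadSet, TranscriptModel, opposite_strand

__all__ = [
    "segment_fragments",
    "merge_extend_luat",
    "luat_tss_offset",
    "quantify_fpkm",
    "assemble_luat",
]


def segment_fragments(
    cov: StrandedCoverage,
    chrom: str,
    strand: str,
    min_cov: int = 1,
    min_len: int = 200,
    window: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Maximal runs of per-base coverage >= ``min_cov``, keeping runs of
    length >= ``min_len``.  Optionally restricted to ``window`` (clipping
    runs at its edges)."""
    vec = cov.data.get((chrom, strand))
    if vec is None:
        return []
    lo, hi = (0, len(vec)) if window is None else (max(0, window[0]), min(len(vec), window[1]))
    if hi <= lo:
        return []
    above = (vec[lo:hi] >= min_cov).astype(np.int8)
    edges = np.diff(np.concatenate([[0], above, [0]]))
    starts = np.flatnonzero(edges == 1) + lo
    ends = np.flatnonzero(edges == -1) + lo
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def _fragment_five_prime(frag: tuple[int, int], strand: str) -> int:
    """5'-most base of a fragment on ``strand`` (right-hand base for minus)."""
    return frag[0] if strand == "+" else frag[1] - 1


def merge_extend_luat(
    fragments: Sequence[tuple[int, int]],
    gene: TranscriptModel,
    seed_window: int = 1500,
    min_len: int = 200,
    max_gap: int = 800,
) -> tuple[int, int] | None:
    """Seed-and-extend merge of antisense fragments into one LUAT span.

    ``fragments`` are intervals on the strand opposite ``gene``.  Fragments
    shorter than ``min_len`` are ignored.  A fragment seeds the model when
    its strand-aware 5' end lies within +/-``seed_window`` of the gene TSS;
    the span then iteratively absorbs fragments whose gap to the current
    span (``next.start - span.end`` on half-open intervals) is strictly
    below ``max_gap``, in both directions until closure.  Returns the final
    ``(start, end)`` span, or ``None`` when no fragment seeds.
    """
    luat_strand = opposite_strand(gene.strand)
    frags = sorted((int(s), int(e)) for s, e in fragments if e - s >= min_len)
    if not frags:
        return None

    seeds = [
        f for f in frags
        if abs(_fragment_five_prime(f, luat_strand) - gene.tss) <= seed_window
    ]
    if not seeds:
        return None
    seed = min(
        seeds,
        key=lambda f: (abs(_fragment_five_prime(f, luat_strand) - gene.tss), f),
    )

    span_s, span_e = seed
    absorbed = {seed}
    changed = True
    while changed:
        changed = False
        for f in frags:
            if f in absorbed:
                continue
            s, e = f
            gap = max(s - span_e, span_s - e, 0)
            if gap < max_gap:
                span_s = min(span_s, s)
                span_e = max(span_e, e)
                absorbed.add(f)
                changed = True
    return (span_s, span_e)


def luat_tss_offset(
    luat_interval: tuple[int, int], gene: TranscriptModel
) -> int:
    """Signed distance of the LUAT 5' end from the gene TSS.

    Negative means the LUAT starts upstream of the gene (in the gene's
    orientation); the LUAT lives on the strand opposite the gene, so its
    5' end is the right-hand base for a plus-strand gene.
    """
    luat_strand = opposite_strand(gene.strand)
    five_p = _fragment_five_prime(tuple(luat_interval), luat_strand)
    if gene.strand == "+":
        return int(five_p - gene.tss)
    return int(gene.tss - five_p)


def quantify_fpkm(
    reads: StrandedReadSet,
    chrom: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    library_size: int,
) -> float:
    """FPKM of a (possibly multi-exon) model.

    ``FPKM = 1e9 * assigned / (exonic_length * library_size)`` where a
    fragment is assigned when it is on the model's strand and overlaps a
    model exon by at least one base.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    exonic_length = sum(e - s for s, e in exons)
    if exonic_length <= 0:
        raise ValueError("model has zero exonic length")
    sub = reads.subset(chrom, strand)
    if sub.empty:
        return 0.0
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    assigned = np.zeros(len(sub), dtype=bool)
    for s, e in exons:
        assigned |= (starts < e) & (ends > s)
    return float(1e9 * assigned.sum() / (exonic_length * library_size))


def assemble_luat(
    cov: StrandedCoverage,
    reads: StrandedReadSet,
    gene: TranscriptModel,
    library_size: int,
    search_span: int = 20000,
    seed_window: int = 1500,
    min_len: int = 200,
    max_gap: int = 800,
    min_cov: int = 1,
) -> tuple[tuple[str, int, int, str], int, float] | None:
    """Segment antisense coverage around a gene's TSS and assemble its LUAT.

    Returns ``((chrom, start, end, strand), offset_bp, fpkm)`` or ``None``
    when no seeded model exists.  ``search_span`` bounds the genomic
    window examined on each side of the TSS.
    """
    luat_strand = opposite_strand(gene.strand)
    window = (max(0, gene.tss - search_span), gene.tss + search_span)
    frags = segment_fragments(cov, gene.chrom, luat_strand, min_cov, min_len, window)
    span = merge_extend_luat(frags, gene, seed_window, min_len, max_gap)
    if span is None:
        return None
    offset = luat_tss_offset(span, gene)
    fpkm = quantify_fpkm(reads, gene.chrom, luat_strand, [span], library_size)
    return ((gene.chrom, span[0], span[1], luat_strand), offset, fpkm)
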