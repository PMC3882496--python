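"""Promoter selection and gene-set construction.

The detection pipeline anchors on coding-gene TSSs.  This module applies
the promoter filters (one representative transcript per TSS cluster, no
other coding gene within the upstream 5 kb) and builds the three
comparison sets used downstream: LUAT-associated genes, head-to-head
coding-coding genes, and expression-matched unidirectional controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GenomeAssembly, TranscriptModel

LABELS = ("luat_associated", "coding_coding", "unidirectional", "excluded")

__all__ = [
    "GeneSetPartition",
    "dedupe_tss",
    "select_candidate_promoters",
    "classify_gene_sets",
    "sample_matched_controls",
    "first_exon_length",
]


@dataclass
class GeneSetPartition:
    """gene_id -> one of luat_associated / coding_coding / unidirectional / excluded."""

    labels: dict[str, str]

    def __post_init__(self):
        bad = {g: l for g, l in self.labels.items() if l not in LABELS}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def genes(self, label: str) -> list[str]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return sorted(g for g, l in self.labels.items() if l == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["gene_id", "label"]
        )


def first_exon_length(t: TranscriptModel) -> int:
    """Length (bp) of the strand-aware first exon."""
    s, e = t.first_exon
    return e - s


def dedupe_tss(
    transcripts: Iterable[TranscriptModel], window: int = 100
) -> list[TranscriptModel]:
    """Collapse each gene's isoforms to one representative per TSS cluster.

    Within a gene, TSSs closer than ``window`` bp (strict) are clustered by
    single linkage along the TSS axis and the longest transcript of each
    cluster is kept (ties broken by lexicographically smallest transcript
    id).  Surviving TSSs of a gene are pairwise >= ``window`` apart.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    kept: list[TranscriptModel] = []
    for gene_ts in by_gene.values():
        gene_ts = sorted(gene_ts, key=lambda t: (t.tss, t.transcript_id))
        clusters: list[list[TranscriptModel]] = []
        for t in gene_ts:
            if clusters and t.tss - clusters[-1][-1].tss < window:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        for cluster in clusters:
            rep = min(
                cluster, key=lambda t: (-(t.end - t.start), t.transcript_id)
            )
            kept.append(rep)
    kept.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return kept


def _upstream_window(t: TranscriptModel, upstream: int) -> tuple[int, int]:
    """Strand-aware upstream interval [a, b) of length ``upstream``, excluding the TSS base."""
    if t.strand == "+":
        return (t.tss - upstream, t.tss)
    return (t.tss + 1, t.tss + 1 + upstream)


def select_candidate_promoters(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeAssembly | Mapping[str, int],
    upstream: int = 5000,
) -> list[TranscriptModel]:
    """Keep coding transcripts whose upstream ``upstream`` bp window is clear.

    A transcript is removed when any coding transcript of another gene —
    on either strand — overlaps its strand-aware upstream window
    (transcription-unit span, not exons only), or when the window runs off
    the chromosome edge.
    """
    lengths = genome.lengths if isinstance(genome, GenomeAssembly) else dict(genome)

    spans: dict[str, list[tuple[int, int, str]]] = {}
    for t in transcripts:
        if not t.is_coding:
            continue
        spans.setdefault(t.chrom, []).append((t.start, t.end, t.gene_id))
    span_arrays = {
        c: (np.array([s for s, e, g in v]), np.array([e for s, e, g in v]),
            np.array([g for s, e, g in v]))
        for c, v in ((c, sorted(v)) for c, v in spans.items())
    }

    kept = []
    for t in transcripts:
        if t.chrom not in lengths:
            raise ValueError(
                f"transcript {t.transcript_id!r} is on unknown chromosome {t.chrom!r}"
            )
        a, b = _upstream_window(t, upstream)
        if a < 0 or b > lengths[t.chrom]:
            continue  # upstream window truncated by chromosome edge
        starts, ends, genes = span_arrays.get(t.chrom, (np.array([]),) * 3)
        if len(starts):
            hit = (starts < b) & (ends > a) & (genes != t.gene_id)
            if hit.any():
                continue
        kept.append(t)
    return kept


def classify_gene_sets(
    candidates: Sequence[TranscriptModel],
    luat_calls: Mapping[str, bool],
    all_transcripts: Sequence[TranscriptModel],
    head_to_head_sep: int = 1500,
    upstream: int = 5000,
) -> GeneSetPartition:
    """Partition candidate genes into the three comparison sets.

    * ``luat_associated`` — LUAT-called genes with a single (deduped) TSS.
    * ``coding_coding`` — genes with an opposite-strand coding gene whose
      TSS lies strictly closer than ``head_to_head_sep`` bp.
    * ``unidirectional`` — genes with no transcript of another gene
      overlapping their upstream window and no LUAT call.
    * everything else — ``excluded``.

    ``candidates`` are deduped transcripts (one per TSS cluster); a gene
    still showing several alternative TSSs after dedup is never labelled
    ``luat_associated``.
    """
    known_genes = {t.gene_id for t in all_transcripts}
    for g in luat_calls:
        if g not in known_genes:
            raise ValueError(f"LUAT call for gene {g!r} absent from annotation")

    coding_tss: list[tuple[str, str, int, str]] = [
        (t.chrom, t.strand, t.tss, t.gene_id) for t in all_transcripts if t.is_coding
    ]

    all_spans: dict[str, list[tuple[int, int, str]]] = {}
    for t in all_transcripts:
        all_spans.setdefault(t.chrom, []).append((t.start, t.end, t.gene_id))

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in candidates:
        by_gene.setdefault(t.gene_id, []).append(t)

    labels: dict[str, str] = {}
    for gene, gene_ts in by_gene.items():
        called = bool(luat_calls.get(gene, False))
        single_tss = len({t.tss for t in gene_ts}) == 1

        head_to_head = any(
            c == t.chrom
            and s != t.strand
            and g != gene
            and abs(p - t.tss) < head_to_head_sep
            for t in gene_ts
            for c, s, p, g in coding_tss
        )

        def _clear(t: TranscriptModel) -> bool:
            a, b = _upstream_window(t, upstream)
            return not any(
                s < b and e > a
                for s, e, g in all_spans.get(t.chrom, [])
                if g != gene
            )

        upstream_clear = all(_clear(t) for t in gene_ts)

        if called:
            labels[gene] = "luat_associated" if single_tss else "excluded"
        elif head_to_head:
            labels[gene] = "coding_coding"
        elif upstream_clear:
            labels[gene] = "unidirectional"
        else:
            labels[gene] = "excluded"
    return GeneSetPartition(labels)


def sample_matched_controls(
    pool: Sequence[str],
    reference_expr: Mapping[str, float],
    pool_expr: Mapping[str, float],
    n: int,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[list[str], float]:
    """Draw ``n`` control genes from ``pool`` matching the reference
    expression distribution.

    The reference expression values define ``n_bins`` equal-count quantile
    bins; control genes are drawn (without replacement) from the pool in
    proportion to the reference bin occupancies.  Returns the sampled gene
    ids and the max |ECDF difference| between control and reference
    expression (a Kolmogorov–Smirnov-style matching diagnostic).
    """
    pool = list(pool)
    ref_ids = list(reference_expr)
    overlap = set(pool) & set(ref_ids)
    if overlap:
        raise ValueError(f"pool and reference overlap: {sorted(overlap)[:5]}")
    if n > len(pool):
        raise ValueError(f"requested {n} controls from a pool of {len(pool)}")

    ref_vals = np.array([reference_expr[g] for g in ref_ids], dtype=float)
    edges = np.quantile(ref_vals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    ref_bin = np.clip(np.searchsorted(edges, ref_vals, side="right") - 1, 0, n_bins - 1)
    pool_vals = np.array([pool_expr[g] for g in pool], dtype=float)
    pool_bin = np.clip(np.searchsorted(edges, pool_vals, side="right") - 1, 0, n_bins - 1)

    # proportional allocation with largest-remainder rounding
    ref_counts = np.bincount(ref_bin, minlength=n_bins).astype(float)
    quota = ref_counts / ref_counts.sum() * n
    take = np.floor(quota).astype(int)
    remainder = quota - take
    short = n - take.sum()
    for b in np.argsort(-remainder)[:short]:
        take[b] += 1

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    order = np.argsort(pool_bin, kind="stable")
    for b in range(n_bins):
        if take[b] == 0:
            continue
        in_bin = [pool[i] for i in order if pool_bin[i] == b]
        if len(in_bin) < take[b]:
            raise ValueError(
                f"expression bin {b} needs {take[b]} controls but the pool has "
                f"{len(in_bin)}; reduce n_bins or n"
            )
        idx = rng.choice(len(in_bin), size=take[b], replace=False)
        chosen.extend(in_bin[i] for i in sorted(idx))

    ctrl_vals = np.sort([pool_expr[g] for g in chosen])
    ref_sorted = np.sort(ref_vals)
    grid = np.unique(np.concatenate([ctrl_vals, ref_sorted]))
    ecdf_c = np.searchsorted(ctrl_vals, grid, side="right") / len(ctrl_vals)
    ecdf_r = np.searchsorted(ref_sorted, grid, side="right") / len(ref_sorted)
    ks = float(np.max(np.abs(ecdf_c - ecdf_r)))
    return chosen, ks
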