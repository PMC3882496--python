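"""Readers and writers for the standard formats the pipeline touches.

GTF is 1-based closed on disk and converted to the internal 0-based
half-open convention on read (and back on write).  BED-family formats are
passed through unchanged.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import FeatureIntervals, GenomeAssembly, StrandedReadSet, TranscriptModel

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_bed12",
    "write_bed12",
    "read_bed6_reads",
    "write_bed6_reads",
    "read_bed_features",
    "write_bed_features",
    "write_fasta",
    "read_jaspar_counts",
    "write_bedgraph",
    "read_bedgraph",
    "write_tsv",
]


# ---------------------------------------------------------------------------
# annotation

def read_gtf(path, coding_feature_types: Sequence[str] = ("exon",)) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features grouped by
    ``transcript_id``/``gene_id`` attributes).

    A transcript is flagged non-coding when its ``gene_biotype`` /
    ``transcript_biotype`` attribute is present and differs from
    ``protein_coding``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.features_of_type(coding_feature_types):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        biotype = (
            feat.attributes.get("transcript_biotype")
            or feat.attributes.get("gene_biotype")
            or ["protein_coding"]
        )[0]
        rec = per_tx.setdefault(
            tid,
            {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": [],
             "is_coding": biotype == "protein_coding"},
        )
        # GTF is 1-based closed; internal is 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))
    models = []
    for tid, rec in per_tx.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                is_coding=rec["is_coding"],
            )
        )
    return models


def write_gtf(path, transcripts: Iterable[TranscriptModel], source: str = "luatscan") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            biotype = "protein_coding" if t.is_coding else "lncRNA"
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{biotype}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_bed12(path, is_coding: bool = True) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if not (len(sizes) == len(offsets) == n_blocks):
                raise ValueError(f"malformed BED12 record for {name!r}")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            gene_id = name.rsplit(".", 1)[0] if "." in name else name
            models.append(
                TranscriptModel(name, gene_id, chrom, strand, exons, is_coding=is_coding)
            )
    return models


def write_bed12(path, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.span
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offsets = ",".join(str(s - start) for s, e in t.exons)
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{t.transcript_id}\t0\t{t.strand}\t"
                f"{start}\t{end}\t0\t{t.n_exons}\t{sizes},\t{offsets},\n"
            )


# ---------------------------------------------------------------------------
# reads / intervals

def read_bed6_reads(path, label: str | None = None) -> StrandedReadSet:
    frame = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return StrandedReadSet(frame, label=label)


def write_bed6_reads(path, reads: StrandedReadSet, name_prefix: str = "frag") -> None:
    f = reads.frame
    with open(path, "w") as fh:
        for i, (chrom, start, end, strand) in enumerate(
            zip(f["chrom"], f["start"], f["end"], f["strand"])
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{name_prefix}{i}\t0\t{strand}\n")


def read_bed_features(path, label: str) -> FeatureIntervals:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            ivs.append((f[0], int(f[1]), int(f[2])))
    return FeatureIntervals(label, ivs)


def write_bed_features(path, features: FeatureIntervals) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(features):
            fh.write(f"{chrom}\t{s}\t{e}\t{features.label}_{i}\n")


# ---------------------------------------------------------------------------
# sequence

def write_fasta(path, genome: GenomeAssembly, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name, 0, genome.length(name))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_jaspar_counts(path_or_handle) -> tuple[str, np.ndarray]:
    """Parse a JASPAR-format count matrix via Bio.motifs.

    Returns ``(motif_id, counts)`` with counts shaped (4, L) in A,C,G,T
    row order.
    """
    from Bio import motifs

    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle)
    try:
        m = motifs.read(handle, "jaspar")
    finally:
        if handle is not path_or_handle:
            handle.close()
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
    name = m.matrix_id or m.name or "motif"
    return name, counts


# ---------------------------------------------------------------------------
# coverage / tables

def write_bedgraph(path, coverage, strand: str) -> None:
    """Write one strand of a StrandedCoverage as run-length bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage.lengths):
            vec = coverage.data.get((chrom, strand))
            if vec is None:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                v = int(vec[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path, coverage, strand: str) -> None:
    """Add bedGraph runs into an existing StrandedCoverage (in place)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            coverage.get(chrom, strand)[int(s) : int(e)] += int(float(v))


def write_tsv(path, frame: pd.DataFrame, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)
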