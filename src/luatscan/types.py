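"""Core domain containers shared across the pipeline.

Coordinates are 0-based, half-open throughout (`[start, end)`, BED
convention).  GTF input is converted on read.  Strands are ``"+"`` and
``"-"``; a transcript's TSS is the strand-aware 5'-most transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")

__all__ = [
    "GenomeAssembly",
    "TranscriptModel",
    "FeatureIntervals",
    "StrandedReadSet",
    "StrandedCoverage",
    "opposite_strand",
]


def opposite_strand(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise ValueError(f"invalid strand: {strand!r}")


class GenomeAssembly:
    """A set of named chromosome sequences (uppercase A/C/G/T/N).

    Sequences are held in memory; synthetic genomes at desk scale are a few
    tens of megabases and fit comfortably.  Use :meth:`from_fasta` for
    on-disk assemblies (loaded through :mod:`pyfaidx`).
    """

    def __init__(self, chroms: Mapping[str, str]):
        if not chroms:
            raise ValueError("GenomeAssembly requires at least one chromosome")
        self._chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            seq = str(seq).upper()
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")
            self._chroms[name] = seq
        self._lengths = {n: len(s) for n, s in self._chroms.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeAssembly":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence of ``chrom[start:end)``; clipped to bounds."""
        seq = self._chroms[chrom]
        return seq[max(0, start) : min(len(seq), end)]

    def validate_alphabet(self) -> None:
        for name, seq in self._chroms.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid bases: {sorted(bad)}")

    def total_bp(self) -> int:
        return sum(self._lengths.values())


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript.

    ``exons`` are 0-based half-open genomic intervals, sorted by start and
    pairwise non-overlapping regardless of strand; strand-aware accessors
    (first exon, TSS, introns) handle the orientation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_coding: bool = True

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if len(exons) == 0:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon [{s},{e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic transcription-unit interval (first exon start to last exon end)."""
        return (self.start, self.end)

    @property
    def tss(self) -> int:
        """Position of the 5'-most transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Introns in 5'->3' transcript order."""
        gaps = tuple(
            (e0, s1) for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:])
        )
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def first_intron(self) -> tuple[int, int]:
        introns = self.introns
        if not introns:
            raise ValueError(f"{self.transcript_id}: transcript has no introns")
        return introns[0]

    def exons_5to3(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class FeatureIntervals:
    """A labelled set of genomic intervals (e.g. CpG islands, conserved elements).

    Intervals are kept sorted per chromosome.  ``merged()`` returns a copy
    with overlapping/adjacent intervals unioned, which makes position
    stabbing via binary search exact.
    """

    def __init__(self, label: str, intervals: Iterable[tuple] = ()):
        self.label = label
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start >= end:
                raise ValueError(f"{label}: empty interval ({chrom},{start},{end})")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._by_chrom: dict[str, np.ndarray] = {
            c: np.array(sorted(ivs), dtype=np.int64) for c, ivs in by_chrom.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) sorted interval array for ``chrom`` (empty if none)."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._by_chrom):
            for s, e in self._by_chrom[chrom]:
                yield (chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._by_chrom.values())

    def merged(self) -> "FeatureIntervals":
        out = []
        for chrom, arr in self._by_chrom.items():
            cur_s, cur_e = None, None
            for s, e in arr:
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e))
        return FeatureIntervals(self.label, out)

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Boolean array: is each position inside >=1 interval?

        Assumes intervals are merged (non-overlapping); call :meth:`merged`
        first if unsure.
        """
        positions = np.asarray(positions, dtype=np.int64)
        arr = self.intervals(chrom)
        if len(arr) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < arr[idx[ok], 1]
        return res

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """(k, 2) intervals overlapping ``[start, end)``."""
        arr = self.intervals(chrom)
        if len(arr) == 0:
            return arr
        keep = (arr[:, 0] < end) & (arr[:, 1] > start)
        return arr[keep]


class StrandedReadSet:
    """Aligned stranded fragments as a (chrom, start, end, strand) table."""

    COLUMNS = ["chrom", "start", "end", "strand"]

    def __init__(self, frame: pd.DataFrame, label: str | None = None):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"read table lacks columns: {missing}")
        frame = frame[self.COLUMNS].reset_index(drop=True)
        if len(frame) and not (frame["start"] < frame["end"]).all():
            raise ValueError("fragment with start >= end")
        if len(frame) and not frame["strand"].isin(STRANDS).all():
            raise ValueError("fragment with undefined strand")
        self.frame = frame
        self.label = label
        self._groups: dict[tuple[str, str], pd.DataFrame] | None = None

    @classmethod
    def from_records(cls, records: Iterable[tuple], label: str | None = None) -> "StrandedReadSet":
        frame = pd.DataFrame(list(records), columns=cls.COLUMNS)
        if frame.empty:
            frame = pd.DataFrame({c: [] for c in cls.COLUMNS})
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        return cls(frame, label=label)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, chrom: str, strand: str) -> pd.DataFrame:
        if self._groups is None:
            self._groups = {
                key: grp for key, grp in self.frame.groupby(["chrom", "strand"], sort=False)
            }
        empty = self.frame.iloc[0:0]
        return self._groups.get((chrom, strand), empty)

    def total_fragment_bp(self) -> int:
        if self.frame.empty:
            return 0
        return int((self.frame["end"] - self.frame["start"]).sum())


@dataclass
class StrandedCoverage:
    """Per-chromosome, per-strand per-base fragment coverage.

    ``data[(chrom, strand)]`` is an int32 vector of length ``len(chrom)``
    where position ``p`` counts fragments with ``start <= p < end``.
    """

    lengths: dict[str, int]
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.data:
            self.data[key] = np.zeros(self.lengths[chrom], dtype=np.int32)
        return self.data[key]

    def total_mass(self, chrom: str | None = None, strand: str | None = None) -> int:
        total = 0
        for (c, s), vec in self.data.items():
            if chrom is not None and c != chrom:
                continue
            if strand is not None and s != strand:
                continue
            total += int(vec.sum())
        return total
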