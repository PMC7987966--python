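"""Genomic interval and sequence data model with FASTA/BED/chrom-sizes I/O.

Coordinates are 0-based, half-open (BED convention) everywhere. An interval's
length is ``end - start``; abutting intervals do not overlap. Strand is carried
on intervals but deliberately ignored by all overlap arithmetic, since ChIP-seq
peaks and the annotation sets they are compared against are unstranded.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}
_NON_ACGTN = re.compile(r"[^ACGTN]")


class GenomeIndex:
    """Ordered map of chromosome name -> length in bp.

    The coordinate universe every :class:`IntervalSet` is validated against.
    Iteration order is the insertion (file) order and is stable.
    """

    def __init__(self, entries: Mapping[str, int] | Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        items = entries.items() if isinstance(entries, Mapping) else entries
        for name, length in items:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[name] = length
        if not self._lengths:
            raise ValueError("GenomeIndex needs at least one chromosome")

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self._lengths == other._lengths

    def items(self):
        return self._lengths.items()

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:
        return f"GenomeIndex({self._lengths!r})"


@dataclass(frozen=True)
class Interval:
    """One genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered list of intervals bound to a :class:`GenomeIndex`."""

    def __init__(self, intervals: Iterable[Interval], genome: GenomeIndex):
        self.intervals: list[Interval] = list(intervals)
        self.genome = genome
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise ValueError(f"interval chrom {iv.chrom!r} absent from genome")
            if iv.end > genome[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {genome[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        order = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(order, self.genome)

    def merged(self) -> "IntervalSet":
        """Union of the set: overlapping or abutting intervals are fused."""
        by_chrom: dict[str, list[Interval]] = defaultdict(list)
        for iv in self.intervals:
            by_chrom[iv.chrom].append(iv)
        out: list[Interval] = []
        for chrom in self.genome:
            ivs = sorted(by_chrom.get(chrom, []), key=lambda iv: (iv.start, iv.end))
            for iv in ivs:
                if out and out[-1].chrom == chrom and iv.start <= out[-1].end:
                    if iv.end > out[-1].end:
                        out[-1] = replace(out[-1], end=iv.end)
                else:
                    out.append(Interval(chrom, iv.start, iv.end))
        return IntervalSet(out, self.genome)

    @property
    def total_covered_bases(self) -> int:
        return sum(iv.length for iv in self.merged())


class OverlapIndex:
    """Interval-tree index over a subject set for repeated overlap queries.

    Built once, queried many times — the workhorse behind overlap counting and
    the permutation null loop.
    """

    def __init__(self, subject: IntervalSet):
        self.genome = subject.genome
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for i, iv in enumerate(subject):
            self._trees[iv.chrom].addi(iv.start, iv.end, i)

    def count(self, iv: Interval, min_overlap: int = 1) -> int:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return 0
        n = 0
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                n += 1
        return n

    def counts(self, query: Iterable[Interval], min_overlap: int = 1) -> np.ndarray:
        return np.array([self.count(iv, min_overlap) for iv in query], dtype=np.int64)

    def hits(self, iv: Interval, min_overlap: int = 1) -> list[int]:
        """Indices (into the subject set) of intervals overlapping ``iv``."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted(
            h.data
            for h in tree.overlap(iv.start, iv.end)
            if min(iv.end, h.end) - max(iv.start, h.begin) >= min_overlap
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> tuple[dict[str, str], GenomeIndex]:
    """Read a FASTA file into an uppercase sequence map plus a GenomeIndex.

    Duplicate record names and empty records are errors. Characters outside
    ACGTN are preserved but flagged in a warning log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        odd = _NON_ACGTN.findall(seq)
        if odd:
            logger.warning(
                "record %s contains %d non-ACGTN characters (e.g. %r)",
                rec.id, len(odd), odd[0],
            )
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs, GenomeIndex({name: len(s) for name, s in seqs.items()})


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeIndex:
    """Two-column <chrom>\\t<length> TSV, an alternative GenomeIndex source."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                entries.append((fields[0], int(fields[1])))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer length") from e
    return GenomeIndex(entries)


def read_bed(path: str | Path, genome: GenomeIndex) -> IntervalSet:
    """Read BED3/BED6 (extra columns ignored); record order preserved.

    Every coordinate violation is reported with its line number.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if end > genome[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: end {end} exceeds {chrom} length {genome[chrom]}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
            intervals.append(Interval(chrom, start, end, name=name, strand=strand))
    return IntervalSet(intervals, genome)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3, or BED6 when any interval carries a name or strand."""
    bed6 = any(iv.name is not None or iv.strand != "." for iv in iset)
    with open(path, "w") as fh:
        for iv in iset:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def extend_clamped(iset: IntervalSet, flank: int) -> IntervalSet:
    """Extend every interval by ``flank`` bp on each side, clamped to its
    chromosome. The interval count never changes."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = [
        replace(
            iv,
            start=max(0, iv.start - flank),
            end=min(iset.genome[iv.chrom], iv.end + flank),
        )
        for iv in iset
    ]
    return IntervalSet(out, iset.genome)


def count_overlaps(
    query: IntervalSet, subject: IntervalSet, min_overlap: int = 1
) -> np.ndarray:
    """Per-query count of subject intervals sharing >= ``min_overlap`` bases.

    Order-independent; strand is ignored.
    """
    if query.genome != subject.genome:
        raise ValueError("query and subject are bound to different genomes")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    return OverlapIndex(subject).counts(query, min_overlap)


def coverage_fraction(iset: IntervalSet, genome: GenomeIndex | None = None) -> float:
    """Fraction of the genome covered by the merged (de-overlapped) set."""
    genome = genome or iset.genome
    return iset.total_covered_bases / genome.total_length
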