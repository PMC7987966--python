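"""Peak classification against repeats, LAD maps, and genomic context.

All membership bookkeeping is non-exclusive: a peak counts in every category
it touches (one peak can contain a combination of repeat elements), so
per-category fractions may sum to more than 1. Exclusive "none of these"
complements are computed from the union of memberships, which conserves the
peak count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import (
    GenomeIndex,
    Interval,
    IntervalSet,
    OverlapIndex,
    coverage_fraction,
)
from .g4_predict import G4Motif, QuadparserParams, find_g4_motifs

_RMSK_COLUMNS = ("genoName", "genoStart", "genoEnd", "repName", "repClass", "repFamily")


@dataclass(frozen=True)
class RepeatRecord:
    """One RepeatMasker annotation row (name is the finest level)."""

    interval: Interval
    repeat_name: str
    repeat_class: str
    repeat_family: str
    milli_div: int | None = None

    def __post_init__(self):
        if not (self.repeat_name and self.repeat_class and self.repeat_family):
            raise ValueError("repeat name/class/family must be non-empty")

    def level(self, level: str) -> str:
        if level == "class":
            return self.repeat_class
        if level == "family":
            return self.repeat_family
        if level == "name":
            return self.repeat_name
        raise ValueError(f"unknown level {level!r}")


@dataclass
class LadMap:
    """Constitutive (cLAD) and facultative (fLAD) lamina-associated domains."""

    clad: IntervalSet
    flad: IntervalSet

    def __post_init__(self):
        if self.clad.genome != self.flad.genome:
            raise ValueError("cLAD and fLAD sets bound to different genomes")


@dataclass
class GenomicContext:
    """Gene bodies, enhancers and CpG islands sharing one genome."""

    gene_bodies: IntervalSet
    enhancers: IntervalSet
    cpg_islands: IntervalSet

    def __post_init__(self):
        g = self.gene_bodies.genome
        if self.enhancers.genome != g or self.cpg_islands.genome != g:
            raise ValueError("context sets bound to different genomes")


def read_rmsk(path, genome: GenomeIndex | None = None) -> list[RepeatRecord]:
    """Read repeat annotations in UCSC rmsk TSV dialect.

    Accepts the full UCSC table (header naming genoName/genoStart/genoEnd/
    repName/repClass/repFamily, extra columns ignored, optional milliDiv
    carried through) or a minimal header-less 6-column dialect
    chrom/start/end/name/class/family. Coordinates are 0-based half-open.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    header = lines[0].lstrip("#").split("\t")
    records: list[RepeatRecord] = []
    if "genoName" in header:
        missing = [c for c in _RMSK_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing rmsk columns {missing}")
        col = {c: header.index(c) for c in header}
        body = lines[1:]
        offset = 2
        idx = [col[c] for c in _RMSK_COLUMNS]
        div_idx = col.get("milliDiv")
    else:
        body = lines
        offset = 1
        idx = [0, 1, 2, 3, 4, 5]
        div_idx = 6 if len(lines[0].split("\t")) > 6 else None
    for lineno, line in enumerate(body, offset):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: fewer than 6 columns")
        chrom = fields[idx[0]]
        try:
            start, end = int(fields[idx[1]]), int(fields[idx[2]])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        if genome is not None and chrom not in genome:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        div = None
        if div_idx is not None and len(fields) > div_idx and fields[div_idx] != "":
            div = int(fields[div_idx])
        records.append(
            RepeatRecord(
                Interval(chrom, start, end, name=fields[idx[3]]),
                repeat_name=fields[idx[3]],
                repeat_class=fields[idx[4]],
                repeat_family=fields[idx[5]],
                milli_div=div,
            )
        )
    return records


def repeats_as_interval_sets(
    repeats: list[RepeatRecord], genome: GenomeIndex, level: str = "family"
) -> dict[str, IntervalSet]:
    """Group repeat records into one IntervalSet per category."""
    groups: dict[str, list[Interval]] = {}
    for rec in repeats:
        groups.setdefault(rec.level(level), []).append(rec.interval)
    return {name: IntervalSet(ivs, genome) for name, ivs in sorted(groups.items())}


def peak_repeat_profile(
    peaks: IntervalSet, repeats: list[RepeatRecord], level: str = "class"
) -> pd.Series:
    """Per-category fraction of peaks containing >= 1 repeat of that category.

    Categories are non-exclusive, so fractions may sum above 1.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    sets = repeats_as_interval_sets(repeats, peaks.genome, level)
    fractions = {}
    for name, iset in sets.items():
        index = OverlapIndex(iset)
        fractions[name] = float((index.counts(peaks) > 0).mean())
    return pd.Series(fractions, dtype=float).sort_index()


def lad_colocalization(peaks: IntervalSet, lads: LadMap) -> dict[str, float]:
    """Fractions of peaks touching cLADs, fLADs, or neither.

    cLAD and fLAD memberships are non-exclusive; nonLAD is the exact
    complement of their union, so nonLAD + (cLAD-or-fLAD membership) = 1.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    in_c = OverlapIndex(lads.clad).counts(peaks) > 0
    in_f = OverlapIndex(lads.flad).counts(peaks) > 0
    return {
        "cLAD": float(in_c.mean()),
        "fLAD": float(in_f.mean()),
        "nonLAD": float((~(in_c | in_f)).mean()),
    }


def genome_repartition(
    features: dict[str, IntervalSet], genome: GenomeIndex
) -> dict[str, float]:
    """Merged coverage fraction per feature name, plus the complement of
    their union under the key ``"complement"``."""
    out = {name: coverage_fraction(iset, genome) for name, iset in features.items()}
    union: list[Interval] = []
    for iset in features.values():
        union.extend(iset)
    union_cov = coverage_fraction(IntervalSet(union, genome), genome) if union else 0.0
    out["complement"] = 1.0 - union_cov
    return out


def genomic_context_profile(
    peaks: IntervalSet, context: GenomicContext
) -> dict[str, float]:
    """Non-exclusive gene-body/enhancer/CpG-island membership fractions."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    in_gene = OverlapIndex(context.gene_bodies).counts(peaks) > 0
    in_enh = OverlapIndex(context.enhancers).counts(peaks) > 0
    in_cpg = OverlapIndex(context.cpg_islands).counts(peaks) > 0
    return {
        "gene_body": float(in_gene.mean()),
        "enhancer": float(in_enh.mean()),
        "cpg_island": float(in_cpg.mean()),
        "none_of_these": float((~(in_gene | in_enh | in_cpg)).mean()),
    }


def compare_peaksets(a: IntervalSet, b: IntervalSet) -> dict[str, int]:
    """Shared/specific peak counts, computed per set.

    ``shared_a`` counts a-peaks touching >= 1 b-peak (and symmetrically), so
    the two shared counts can differ: one very large peak in one set may
    contain several peaks of the other.
    """
    if a.genome != b.genome:
        raise ValueError("peak sets bound to different genomes")
    shared_a = int((OverlapIndex(b).counts(a) > 0).sum())
    shared_b = int((OverlapIndex(a).counts(b) > 0).sum())
    return {
        "specific_a": len(a) - shared_a,
        "shared_a": shared_a,
        "specific_b": len(b) - shared_b,
        "shared_b": shared_b,
    }


def consensus_g4_count(
    consensus: dict[str, str], params: QuadparserParams
) -> dict[str, list[G4Motif]]:
    """Scan repeat consensus sequences for G4 motifs (both strands).

    Motif coordinates are relative to each consensus.
    """
    out = {}
    for name, seq in consensus.items():
        if not seq:
            raise ValueError(f"empty consensus sequence {name!r}")
        out[name] = find_g4_motifs(seq, params, strands="both")
    return out
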