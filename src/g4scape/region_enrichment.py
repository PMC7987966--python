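"""Permutation-based significance of peak/feature colocalization.

The null model repositions every peak uniformly at random on the genome
(width preserved, chromosome drawn proportionally to the number of valid
start positions) and recomputes the colocalization statistic. Significance is
reported as an empirical p-value with the standard +1 finite-permutation
correction, alongside a Z-score against the permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeIndex,
    Interval,
    IntervalSet,
    OverlapIndex,
    extend_clamped,
)

STATISTICS = ("fraction_overlapping", "total_overlap_count")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic against its permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_emp: float
    n_perm: int
    seed: int | None
    statistic_name: str
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_emp": self.p_emp,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "statistic_name": self.statistic_name,
            "degenerate": self.degenerate,
        }


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _FeatureArrays:
    """Per-chromosome sorted start/end arrays for vectorized overlap counts.

    For half-open intervals and min_overlap = 1, the number of features
    overlapping a query [s, e) is #(feature starts < e) - #(feature ends <= s),
    since every feature ending at or before s also starts before e.
    """

    def __init__(self, feature: IntervalSet, names: list[str]):
        self.by_chrom = []
        for chrom in names:
            starts = np.sort([iv.start for iv in feature if iv.chrom == chrom])
            ends = np.sort([iv.end for iv in feature if iv.chrom == chrom])
            self.by_chrom.append((starts, ends))

    def counts(self, ci: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        out = np.zeros(len(starts), dtype=np.int64)
        for c, (fs, fe) in enumerate(self.by_chrom):
            mask = ci == c
            if len(fs) and mask.any():
                out[mask] = np.searchsorted(fs, ends[mask], "left") - np.searchsorted(
                    fe, starts[mask], "right"
                )
        return out


def _stat_from_counts(counts: np.ndarray, statistic: str) -> float:
    if statistic == "fraction_overlapping":
        return float((counts > 0).mean())
    if statistic == "total_overlap_count":
        return float(counts.sum())
    raise ValueError(f"unknown statistic {statistic!r}")


class _NullSampler:
    """Vectorized width-preserving randomization shared by the null loops."""

    def __init__(self, peaks: IntervalSet, genome: GenomeIndex, flank: int):
        self.names = genome.names
        self.lengths = np.array([genome[c] for c in self.names], dtype=np.int64)
        self.widths = np.array([iv.length for iv in peaks], dtype=np.int64)
        uniq_w, self.inv = np.unique(self.widths, return_inverse=True)
        slots = np.maximum(self.lengths[None, :] - uniq_w[:, None] + 1, 0)
        totals = slots.sum(axis=1)
        if (totals == 0).any():
            bad = int(uniq_w[np.argmax(totals == 0)])
            raise ValueError(f"interval width {bad} exceeds every chromosome")
        self.cum = np.cumsum(slots / totals[:, None], axis=1)
        self.flank = flank

    def draw(self, rng: np.random.Generator):
        ci = (rng.random(len(self.widths))[:, None] > self.cum[self.inv]).sum(axis=1)
        starts = rng.integers(0, self.lengths[ci] - self.widths + 1)
        ext_s = np.maximum(starts - self.flank, 0)
        ext_e = np.minimum(starts + self.widths + self.flank, self.lengths[ci])
        return ci, ext_s, ext_e


def randomize_regions(
    iset: IntervalSet, genome: GenomeIndex | None = None, rng_seed=None
) -> IntervalSet:
    """Randomly reposition every interval, preserving its width.

    For an interval of width w, the chromosome is drawn with probability
    proportional to (length - w + 1) over chromosomes that can host it, and
    the start uniformly over valid positions. Outputs may overlap each other.
    """
    genome = genome or iset.genome
    rng = _as_rng(rng_seed)
    names = genome.names
    lengths = np.array([genome[c] for c in names], dtype=np.int64)
    widths = np.array([iv.length for iv in iset], dtype=np.int64)
    uniq_w, inv = np.unique(widths, return_inverse=True)
    slots = np.maximum(lengths[None, :] - uniq_w[:, None] + 1, 0)  # (W, C)
    totals = slots.sum(axis=1)
    if (totals == 0).any():
        bad = int(uniq_w[np.argmax(totals == 0)])
        raise ValueError(f"interval width {bad} exceeds every chromosome")
    cum = np.cumsum(slots / totals[:, None], axis=1)
    ci = (rng.random(len(widths))[:, None] > cum[inv]).sum(axis=1)
    starts = rng.integers(0, lengths[ci] - widths + 1)
    out = [
        Interval(names[c], int(s), int(s + w))
        for c, s, w in zip(ci, starts, widths)
    ]
    return IntervalSet(out, genome)


def _evaluate(
    peaks: list[Interval], index: OverlapIndex, statistic: str, min_overlap: int = 1
) -> float:
    counts = index.counts(peaks, min_overlap)
    if statistic == "fraction_overlapping":
        return float((counts > 0).mean())
    if statistic == "total_overlap_count":
        return float(counts.sum())
    raise ValueError(f"unknown statistic {statistic!r}")


def _summarize(
    observed: float,
    nulls: np.ndarray,
    statistic: str,
    seed,
    alternative: str,
) -> PermutationResult:
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
    degenerate = null_sd == 0.0
    z = 0.0 if degenerate else (observed - null_mean) / null_sd
    n_perm = len(nulls)
    if alternative == "enrichment":
        extreme = int((nulls >= observed).sum())
    elif alternative == "depletion":
        extreme = int((nulls <= observed).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p_emp = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        observed, null_mean, null_sd, z, p_emp, n_perm,
        seed if isinstance(seed, (int, type(None))) else None,
        statistic, degenerate,
    )


def permutation_enrichment(
    peaks: IntervalSet,
    feature: IntervalSet,
    statistic: str = "fraction_overlapping",
    n_perm: int = 1000,
    flank: int = 0,
    rng_seed=None,
    alternative: str = "enrichment",
) -> PermutationResult:
    """Permutation test of peak/feature colocalization.

    The observed statistic is computed on the flank-extended peaks; each of
    ``n_perm`` permutations repositions the (unextended) peaks at random,
    applies the same flank, and recomputes the statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(peaks) == 0 or len(feature) == 0:
        raise ValueError("peaks and feature set must be non-empty")
    rng = _as_rng(rng_seed)
    index = OverlapIndex(feature)
    observed = _evaluate(list(extend_clamped(peaks, flank)), index, statistic)
    sampler = _NullSampler(peaks, peaks.genome, flank)
    arrays = _FeatureArrays(feature, sampler.names)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        ci, s, e = sampler.draw(rng)
        nulls[i] = _stat_from_counts(arrays.counts(ci, s, e), statistic)
    return _summarize(observed, nulls, statistic,
                      rng_seed if isinstance(rng_seed, int) else None, alternative)


def multi_feature_enrichment(
    peaks: IntervalSet,
    features: dict[str, IntervalSet],
    statistic: str = "fraction_overlapping",
    n_perm: int = 1000,
    flank: int = 0,
    rng_seed=None,
    alternative: str = "enrichment",
) -> pd.DataFrame:
    """One permutation test per named feature set, sharing the null probes.

    Permutation i uses the same randomized peak set for every feature, so the
    per-feature columns are directly comparable. Returns a DataFrame with one
    row per feature (columns: observed, null_mean, null_sd, z, p_emp, n_perm,
    seed, statistic_name, degenerate), serializable to TSV.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    rng = _as_rng(rng_seed)
    names = list(features)
    if not names:
        df = pd.DataFrame(
            columns=["observed", "null_mean", "null_sd", "z", "p_emp",
                     "n_perm", "seed", "statistic_name", "degenerate"]
        )
        df.index.name = "feature"
        return df
    indexes = {name: OverlapIndex(features[name]) for name in names}
    observed = {}
    ext_peaks = list(extend_clamped(peaks, flank))
    for name in names:
        observed[name] = _evaluate(ext_peaks, indexes[name], statistic)
    sampler = _NullSampler(peaks, peaks.genome, flank)
    arrays = {name: _FeatureArrays(features[name], sampler.names) for name in names}
    nulls = {name: np.empty(n_perm) for name in names}
    for i in range(n_perm):
        ci, s, e = sampler.draw(rng)
        for name in names:
            nulls[name][i] = _stat_from_counts(
                arrays[name].counts(ci, s, e), statistic
            )
    rows = {
        name: _summarize(
            observed[name], nulls[name], statistic,
            rng_seed if isinstance(rng_seed, int) else None, alternative,
        ).as_dict()
        for name in names
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature"
    return df
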