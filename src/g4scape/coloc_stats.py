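"""Quantification statistics for imaging-derived intensity data.

Consumes intensity values already extracted from micrographs (line-profile
pairs and per-cell mean nuclear intensities); image segmentation itself is
out of scope. Provides line-profile Pearson colocalization, per-cell K-means
grouping with per-cluster correlations, and box-plot summaries whose center
line is the mean (the convention the source figures use), not the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass
class PairedIntensity:
    """Two same-length intensity profiles from one drawn line / cell."""

    a: np.ndarray
    b: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.ndim != 1 or self.b.ndim != 1 or len(self.a) != len(self.b):
            raise ValueError("paired profiles must be 1-D and of equal length")
        if len(self.a) < 3:
            raise ValueError("paired profiles need >= 3 points")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("profiles must be finite")


def read_paired_profiles(path) -> list[PairedIntensity]:
    """TSV with columns label, position, channel_a, channel_b."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "position", "channel_a", "channel_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("position")
        out.append(
            PairedIntensity(grp.channel_a.to_numpy(), grp.channel_b.to_numpy(),
                            label=str(label))
        )
    return out


def read_cell_table(path) -> pd.DataFrame:
    """TSV of per-cell mean nuclear intensities: cell_id + one column/marker."""
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: missing cell_id column")
    return df.set_index("cell_id")


def pearson_profile(p: PairedIntensity) -> float:
    """Pearson correlation between the two channels of a paired profile."""
    if np.std(p.a) == 0 or np.std(p.b) == 0:
        raise ValueError("zero-variance channel: Pearson r undefined")
    return float(pearsonr(p.a, p.b).statistic)


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(pearsonr(x, y).statistic)


def kmeans_cells(
    table: pd.DataFrame, k: int, n_iter: int = 20, seed: int | None = None
) -> tuple[np.ndarray, dict[int, float]]:
    """Group cells by marker intensity with Lloyd's K-means.

    Centers are initialized as k distinct data rows drawn by ``seed`` with
    distance-weighted (k-means++-style) seeding, then exactly ``n_iter``
    update rounds are run, exiting early once assignments stop changing.
    Deterministic for a fixed seed. Returns per-cell labels and, per cluster,
    the Pearson r between the first two marker columns.
    """
    X = table.to_numpy(dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} rows available")
    rng = np.random.default_rng(seed)
    # k-means++ seeding over the data rows: first uniform, then proportional
    # to squared distance from the nearest chosen center
    chosen = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = np.min(
            ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        if d2.sum() == 0:  # all remaining points identical to a center
            remaining = [i for i in range(n) if i not in chosen]
            chosen.append(int(rng.choice(remaining)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / d2.sum())))
    centers = X[chosen].copy()
    labels = np.full(n, -1)
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    per_cluster_r = {}
    if table.shape[1] >= 2:
        for j in range(k):
            members = X[labels == j]
            per_cluster_r[j] = _pearson_or_nan(members[:, 0], members[:, 1])
    return labels, per_cluster_r


def within_cluster_ss(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squares (diagnostic for K-means runs)."""
    X = np.asarray(X, dtype=float)
    total = 0.0
    for j in np.unique(labels):
        members = X[labels == j]
        total += ((members - members.mean(axis=0)) ** 2).sum()
    return float(total)


def box_stats(values) -> dict[str, float]:
    """Box-plot summary: whiskers at min/max, box at the 25th and 75th
    percentiles (linear interpolation), center line at the MEAN."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return {
        "min": float(v.min()),
        "q25": float(np.percentile(v, 25)),
        "mean": float(v.mean()),
        "q75": float(np.percentile(v, 75)),
        "max": float(v.max()),
    }
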