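"""Clustering of length-normalized grain-set-ratio profiles.

Ears of different lengths are compared on a common relative-position grid:
each smoothed GSR profile is interpolated onto ``n_points`` positions on
[0, 1] (0 = base, 1 = apex) and the per-view profiles of an ear are
averaged.  Ears are then clustered on the Euclidean distance between
profiles — Ward agglomeration by default, k-means as an alternative
backend — and clusters are relabelled 1..k by decreasing mean profile
integral, so cluster 1 is always the least aborted and cluster k the most,
whatever arbitrary labels the backend returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f_oneway
from sklearn.cluster import KMeans

from .abortion import GSRProfile

__all__ = [
    "NormalizedProfileMatrix",
    "ClusterResult",
    "normalize_profile",
    "average_sides",
    "cluster_profiles",
    "cluster_summaries",
]


@dataclass
class NormalizedProfileMatrix:
    """Ears x relative positions matrix of GSR values."""

    values: np.ndarray                 # (n_ears, n_points), in [0, 1]
    positions: np.ndarray              # shared grid on [0, 1]
    ear_ids: list[str]
    treatments: list[str] | None = None
    ear_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.ear_ids):
            raise ValueError("one ear id per matrix row required")
        if self.values.shape[1] != len(self.positions):
            raise ValueError("matrix columns must match the position grid")


@dataclass
class ClusterResult:
    """Cluster labels (1..k, 1 = least aborted) and per-cluster summaries."""

    labels: np.ndarray                 # int per ear
    k: int
    method: str
    mean_profiles: np.ndarray          # (k, n_points)
    std_profiles: np.ndarray
    linkage_matrix: np.ndarray | None  # Ward tree (None for k-means)
    ear_ids: list[str]


def normalize_profile(profile: GSRProfile, ear_length_cm: float,
                      n_points: int = 100) -> np.ndarray:
    """Interpolate a (smoothed) profile onto ``n_points`` relative positions.

    Positions along the ear are divided by the ear length so ears of
    different sizes are comparable; a single-row profile yields a constant
    vector.  ``ear_length_cm`` is accepted for interface symmetry — the
    relative grid only needs the profile's own row span.
    """
    values = profile.values
    if len(values) == 0:
        raise ValueError("cannot normalize an empty profile")
    grid = np.linspace(0.0, 1.0, n_points)
    if len(values) == 1:
        return np.full(n_points, float(values[0]))
    rel = np.linspace(0.0, 1.0, len(values))    # bottom -> top
    return np.interp(grid, rel, values)


def average_sides(view_profiles: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean of the per-view normalized profiles of one ear."""
    if not view_profiles:
        raise ValueError("at least one view profile required")
    stacked = np.vstack(view_profiles)
    return stacked.mean(axis=0)


def cluster_profiles(matrix: NormalizedProfileMatrix, k: int = 5,
                     method: str = "ward", seed: int = 0) -> ClusterResult:
    """Cluster ears by their normalized GSR profiles.

    ``method='ward'`` builds a Ward tree on Euclidean distances and cuts it
    into ``k`` clusters; ``method='kmeans'`` runs seeded k-means.  Input
    order does not matter: rows are processed in ear-id order and labels
    mapped back, and the final labels are 1..k by decreasing mean profile
    integral.
    """
    n = matrix.values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of ears ({n})")
    if method not in ("ward", "kmeans"):
        raise ValueError("method must be 'ward' or 'kmeans'")
    order = np.argsort(np.asarray(matrix.ear_ids, dtype=object))
    x = matrix.values[order]
    tree = None
    if method == "ward":
        tree = linkage(x, method="ward", metric="euclidean")
        raw = fcluster(tree, t=k, criterion="maxclust")
    else:
        raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x) + 1
    labels_sorted = np.asarray(raw, dtype=int)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted

    # relabel 1..k by decreasing mean-profile integral (1 = least aborted);
    # a degenerate tree can yield fewer than k occupied clusters
    def _mean(lab):
        members = matrix.values[labels == lab]
        return members.mean(axis=0) if len(members) else np.zeros(matrix.values.shape[1])

    integrals = np.array([
        np.trapezoid(_mean(lab), matrix.positions) if np.any(labels == lab)
        else -np.inf
        for lab in range(1, k + 1)
    ])
    new_of_old = np.empty(k, dtype=int)
    new_of_old[np.argsort(-integrals, kind="stable")] = np.arange(1, k + 1)
    labels = new_of_old[labels - 1]

    mean_profiles = np.vstack([_mean(lab) for lab in range(1, k + 1)])
    std_profiles = np.vstack([
        matrix.values[labels == lab].std(axis=0) if np.any(labels == lab)
        else np.zeros(matrix.values.shape[1])
        for lab in range(1, k + 1)
    ])
    return ClusterResult(labels=labels, k=k, method=method,
                         mean_profiles=mean_profiles, std_profiles=std_profiles,
                         linkage_matrix=tree, ear_ids=list(matrix.ear_ids))


def cluster_summaries(result: ClusterResult,
                      treatments: list[str] | None = None,
                      ear_lengths: np.ndarray | None = None) -> dict:
    """Per-cluster treatment proportions, ear lengths, and a length ANOVA.

    Treatment proportions are P(cluster | treatment): within each treatment
    group they sum to 1.  The one-way ANOVA tests ear length across
    clusters (F and p are NaN with fewer than two clusters).
    """
    labels = result.labels
    out: dict = {"k": result.k, "cluster_sizes": {
        int(lab): int(np.sum(labels == lab)) for lab in range(1, result.k + 1)
    }}
    if treatments is not None:
        treatments = list(treatments)
        table = pd.crosstab(pd.Series(labels, name="cluster"),
                            pd.Series(treatments, name="treatment"))
        table = table.reindex(range(1, result.k + 1), fill_value=0)
        props = table / table.sum(axis=0)
        out["treatment_proportions"] = {
            str(t): {int(lab): float(props.loc[lab, t]) for lab in props.index}
            for t in props.columns
        }
    if ear_lengths is not None:
        lengths = np.asarray(ear_lengths, dtype=float)
        ok = np.isfinite(lengths)
        out["n_with_length"] = int(ok.sum())
        out["mean_length_cm"] = {}
        out["sd_length_cm"] = {}
        groups = []
        for lab in range(1, result.k + 1):
            vals = lengths[ok & (labels == lab)]
            out["mean_length_cm"][int(lab)] = float(vals.mean()) if vals.size else float("nan")
            out["sd_length_cm"][int(lab)] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            if vals.size:
                groups.append(vals)
        if len(groups) >= 2:
            f_stat, p_val = f_oneway(*groups)
            out["anova_F"], out["anova_p"] = float(f_stat), float(p_val)
        else:
            out["anova_F"] = out["anova_p"] = float("nan")
    return out
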