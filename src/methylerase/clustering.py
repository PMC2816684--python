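"""Discovery of the arrest-induced erasure cluster and course-specificity calls.

The workflow mirrors the standard profile-clustering recipe for synchronized
time courses: k-means (k = 6) on zero-centered, concatenated profiles, then
membership extension by Pearson correlation (r >= 0.5) to the focal cluster's
mean profile, then classification of each nucleosome by which synchrony
protocol elicits the erasure profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import MatrixValidationError
from .track_io import TimeCourseMatrix


@dataclass
class ClusterResult:
    k: int
    assignments: Dict[str, int]
    centroids: np.ndarray            # k x n_times, row c = mean of members
    inertia: float
    seed: int
    n_restarts: int
    r_min: Optional[float] = None
    extended_membership: Set[str] = field(default_factory=set)
    excluded_zero_variance: List[str] = field(default_factory=list)

    def members(self, cluster: int) -> List[str]:
        return [rid for rid, c in self.assignments.items() if c == cluster]


def kmeans_profiles(matrix: TimeCourseMatrix, k: int, seed: int = 0,
                    n_restarts: int = 50) -> ClusterResult:
    """Euclidean k-means on row profiles; best of ``n_restarts`` by WCSS.

    Rows are canonicalized to id-sorted order before clustering, so permuting
    the input rows permutes the assignments identically.  Missing cells are
    rejected (impute or drop first).
    """
    if k > matrix.n_rows:
        raise MatrixValidationError(
            f"k = {k} exceeds the number of rows ({matrix.n_rows})")
    if not np.all(np.isfinite(matrix.values)):
        raise MatrixValidationError(
            "matrix contains missing cells; impute by row mean or drop first")
    order = np.argsort(np.asarray(matrix.ids, dtype=object))
    x = matrix.values[order]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    labels_sorted = km.fit_predict(x)
    assignments = {matrix.ids[idx]: int(lab)
                   for idx, lab in zip(order, labels_sorted)}
    # recompute centroids as exact member means (KMeans' centers already are,
    # but recomputing keeps the invariant independent of the fitter)
    centroids = np.vstack([
        x[labels_sorted == c].mean(axis=0) for c in range(k)
    ])
    return ClusterResult(k=k, assignments=assignments, centroids=centroids,
                         inertia=float(km.inertia_), seed=seed,
                         n_restarts=n_restarts)


def pearson_to_profile(matrix: TimeCourseMatrix, profile: np.ndarray,
                       columns: Optional[slice] = None
                       ) -> Tuple[pd.Series, List[str]]:
    """Pearson r of every row against ``profile``.

    Zero-variance rows are excluded and reported, not assigned r = 0.
    Returns (r by id over finite-variance rows, excluded ids).
    """
    profile = np.asarray(profile, dtype=float)
    values = matrix.values if columns is None else matrix.values[:, columns]
    if len(profile) != values.shape[1] or len(profile) < 3:
        raise MatrixValidationError(
            f"profile length {len(profile)} incompatible with matrix "
            f"({values.shape[1]} columns; need >= 3)")
    p = profile - profile.mean()
    p_norm = np.sqrt((p ** 2).sum())
    if p_norm == 0:
        raise MatrixValidationError("zero-variance centroid profile")
    v = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((v ** 2).sum(axis=1))
    ok = norms > 0
    r = np.full(len(norms), np.nan)
    r[ok] = v[ok] @ p / (norms[ok] * p_norm)
    excluded = [matrix.ids[i] for i in np.where(~ok)[0]]
    series = pd.Series(r[ok], index=[matrix.ids[i] for i in np.where(ok)[0]])
    return series, excluded


def extend_cluster_by_correlation(matrix: TimeCourseMatrix,
                                  centroid: np.ndarray, r_min: float = 0.5,
                                  columns: Optional[slice] = None
                                  ) -> Tuple[Set[str], List[str]]:
    """Ids whose Pearson correlation with ``centroid`` is >= ``r_min``.

    ``columns`` restricts the comparison to one concatenation segment (the
    extension is done per course).  Returns (ids, zero-variance exclusions).
    """
    r, excluded = pearson_to_profile(matrix, centroid, columns)
    # tolerance so that exactly proportional rows pass r_min = 1.0
    return set(r.index[r >= r_min - 1e-12]), excluded


def cluster6_template(times: np.ndarray, s_window: Tuple[float, float]
                      ) -> np.ndarray:
    """Step template of the erasure signature: high before the S-phase
    midpoint, low after."""
    times = np.asarray(times, dtype=float)
    mid = 0.5 * (s_window[0] + s_window[1])
    return np.where(times < mid, 1.0, -1.0)


def find_focal_cluster(result: ClusterResult, template: np.ndarray,
                       columns: Optional[slice] = None) -> int:
    """Index of the centroid best matching the erasure template (Pearson r).

    On real data the erasure cluster was picked by eye; on synthetic data the
    template (high pre-S, low post-S) makes the choice reproducible.
    """
    template = np.asarray(template, dtype=float)
    best, best_r = 0, -np.inf
    for c in range(result.k):
        cen = result.centroids[c] if columns is None else result.centroids[c][columns]
        t = template - template.mean()
        v = cen - cen.mean()
        denom = np.sqrt((t ** 2).sum() * (v ** 2).sum())
        r = float(v @ t / denom) if denom > 0 else -np.inf
        if r > best_r:
            best, best_r = c, r
    return best


def classify_course_specificity(r_a: Mapping[str, float],
                                r_ts: Mapping[str, float],
                                margin: float = 0.2
                                ) -> Tuple[pd.Series, List[str]]:
    """Label each id TS>A / A>TS / TS~A by the correlation difference.

    Returns (labels by id, ids sorted by decreasing ``r_ts - r_a``), the sort
    the heatmap ordering uses.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    r_a = pd.Series(r_a)
    r_ts = pd.Series(r_ts)
    common = r_a.index.intersection(r_ts.index)
    if len(common) == 0:
        raise ValueError("no ids with both correlations defined")
    diff = (r_ts.loc[common] - r_a.loc[common]).astype(float)
    labels = pd.Series("TS~A", index=common, dtype=object)
    labels[diff > margin] = "TS>A"
    labels[diff < -margin] = "A>TS"
    order = diff.sort_values(ascending=False).index.tolist()
    return labels, order


def group_induction_summary(groups: Mapping[str, str],
                            induction: Mapping[str, float]) -> pd.DataFrame:
    """Per-group mean and SEM of an induction covariate (missing values skipped)."""
    groups = pd.Series(groups)
    induction = pd.Series(induction, dtype=float)
    rows = []
    for name, ids in groups.groupby(groups).groups.items():
        vals = induction.reindex(ids).dropna()
        if len(vals) == 0:
            raise ValueError(f"group {name!r} has no induction values")
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"group": name, "n": int(len(vals)),
                     "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows).set_index("group")
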