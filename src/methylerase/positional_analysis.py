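"""Probe-level loss filters and TSS-distance summaries.

These distinguish 5' active demethylation (release-independent) from 3'
replication-dependent clearance.  Loss percentages are on the linear (fold)
scale: a log2 change of ``delta`` is a loss of ``100 * (1 - 2**delta)``
percent, so "over 40%" means ``2**delta < 0.6``.  Boundary semantics follow
the defining rules literally: "over 40%" is strict, "75% or more" inclusive,
"log2 > 0.75" strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .errors import MatrixValidationError
from .track_io import TimeCourseMatrix


@dataclass
class FilterReport:
    """Accounting of one filter pass: retained + removed partitions the input."""

    rule: str
    retained: List[str]
    removed: Dict[str, str]      # id -> reason

    @property
    def retained_set(self) -> Set[str]:
        return set(self.retained)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"nucleosome_id": rid, "status": "retained", "reason": ""}
                for rid in self.retained]
        rows += [{"nucleosome_id": rid, "status": "removed", "reason": why}
                 for rid, why in self.removed.items()]
        return pd.DataFrame(rows)


def _column(matrix: TimeCourseMatrix, t: float) -> np.ndarray:
    times = np.asarray(matrix.times, dtype=float)
    matches = np.where(np.isclose(times, t))[0]
    if len(matches) == 0:
        raise MatrixValidationError(f"time point {t} absent from the grid")
    return matrix.values[:, matches[0]]


def loss_percent(matrix: TimeCourseMatrix, t_from: float, t_to: float
                 ) -> pd.Series:
    """Linear-scale percent loss between two time points, per row."""
    if matrix.centered:
        raise MatrixValidationError("loss filters require uncentered log2 values")
    delta = _column(matrix, t_to) - _column(matrix, t_from)
    return pd.Series(100.0 * (1.0 - 2.0 ** delta), index=matrix.ids)


def filter_by_loss(matrix: TimeCourseMatrix, t_from: float, t_to: float,
                   min_loss_percent: float = 40.0
                   ) -> Tuple[Set[str], FilterReport]:
    """Retain probes with linear-scale loss strictly over ``min_loss_percent``."""
    loss = loss_percent(matrix, t_from, t_to)
    retained = loss.index[loss > min_loss_percent].tolist()
    removed = {rid: f"loss {loss[rid]:.1f}% <= {min_loss_percent}%"
               for rid in loss.index if loss[rid] <= min_loss_percent}
    report = FilterReport(
        rule=f"loss({t_from}->{t_to}) > {min_loss_percent}% "
             f"(log2 delta < {np.log2(1 - min_loss_percent / 100.0):.4f})",
        retained=retained, removed=removed)
    return set(retained), report


def filter_strong_erasure(matrix: TimeCourseMatrix, t_from: float = 0.0,
                          horizon: float = 75.0,
                          min_loss_percent: float = 75.0
                          ) -> Tuple[Set[str], FilterReport]:
    """Retain probes with loss of ``min_loss_percent`` *or more* (inclusive)."""
    loss = loss_percent(matrix, t_from, horizon)
    retained = loss.index[loss >= min_loss_percent].tolist()
    removed = {rid: f"loss {loss[rid]:.1f}% < {min_loss_percent}%"
               for rid in loss.index if loss[rid] < min_loss_percent}
    report = FilterReport(
        rule=f"loss({t_from}->{horizon}) >= {min_loss_percent}%",
        retained=retained, removed=removed)
    return set(retained), report


def exclude_confounded(values_a: Mapping[str, float],
                       values_b: Mapping[str, float],
                       max_diff_log2: float = 0.75
                       ) -> Tuple[Set[str], FilterReport]:
    """Remove ids where condition A exceeds condition B by strictly more than
    ``max_diff_log2`` (e.g. alpha+galactose arrest vs midlog+galactose)."""
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    if set(a.index) != set(b.index):
        raise MatrixValidationError("exclude_confounded: id sets differ")
    diff = a - b.loc[a.index]
    retained = diff.index[~(diff > max_diff_log2)].tolist()
    removed = {rid: f"diff {diff[rid]:.2f} > {max_diff_log2}"
               for rid in diff.index if diff[rid] > max_diff_log2}
    report = FilterReport(rule=f"condA - condB > {max_diff_log2} removed",
                          retained=retained, removed=removed)
    return set(retained), report


def running_window_mean(values: Sequence[float], window: int = 50) -> np.ndarray:
    """Centered moving mean with truncated (shrinking) windows at the edges.

    The caller supplies values already sorted by the ordering key (arrest
    hypermethylation, TSS distance, ...).  Output length equals input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    n = len(x)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def tss_distance_profile(loss: Mapping[str, float],
                         tss_distance: Mapping[str, float],
                         cluster_labels: Mapping[str, Union[int, str]],
                         bin_edges: Sequence[float]) -> pd.DataFrame:
    """Per-cluster mean loss versus TSS distance, over caller-defined bins.

    Returns a frame indexed by cluster with one column per distance bin
    (NaN where a cluster has no probe in a bin).  Raises on an empty cluster.
    """
    loss = pd.Series(loss, dtype=float)
    dist = pd.Series(tss_distance, dtype=float).loc[loss.index]
    labels = pd.Series(cluster_labels).loc[loss.index]
    if (dist < 0).any():
        raise MatrixValidationError("tss distances must be >= 0")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 values")
    names = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    rows = {}
    for cluster, ids in labels.groupby(labels).groups.items():
        if len(ids) == 0:
            raise ValueError(f"cluster {cluster!r} is empty")
        which = np.digitize(dist.loc[ids], edges) - 1
        row = {}
        for b, name in enumerate(names):
            sel = [rid for rid, w in zip(ids, which) if w == b]
            row[name] = float(loss.loc[sel].mean()) if sel else float("nan")
        rows[cluster] = row
    return pd.DataFrame.from_dict(rows, orient="index")[names]
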