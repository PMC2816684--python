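"""Quantification of S-phase methylation loss and its replication dependence.

Operates on baseline-differenced log2 matrices (positive = above midlog).  The
erasure fraction of a locus at horizon ``h`` is defined on the log2-excess
scale::

    E(h) = (arrest_value - value(h)) / arrest_value

so E = 0 for an unchanged locus, E = 1 at full reversion to baseline, and
E > 1 for transient overshoot below baseline after a dilution event.

Panel-level replication dependence compares paired replicating /
non-replicating arms: the residual ratio ``100 * mean(E_norep) / mean(E_rep)``
and the complementary percent decrease.  Because per-locus denominators are
noisy near zero, panel aggregates are computed on the panel-mean profile
(see :func:`panel_erasure_fraction`); per-locus values remain available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import MatrixValidationError
from .track_io import NucleosomeTrack, TimeCourseMatrix, join


def sphase_drop(series: np.ndarray, times: np.ndarray,
                s_window: Tuple[float, float]) -> Tuple[float, float]:
    """Mean(pre-window) - mean(post-window) of a log2 series, and its fold.

    Window means (rather than single time points) damp measurement noise.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    pre = series[times < s_window[0]]
    post = series[times > s_window[1]]
    if len(pre) == 0 or len(post) == 0:
        raise MatrixValidationError(
            f"series must cover both sides of the S window {s_window}")
    drop = float(np.nanmean(pre) - np.nanmean(post))
    return drop, float(2.0 ** drop)


def drop_time(series: np.ndarray, times: np.ndarray,
              threshold: Optional[float] = None, sustain: int = 1) -> float:
    """Linearly interpolated first crossing of (start value - threshold).

    ``threshold`` defaults to half the total loss (start minus end).  A series
    with no net loss, or that never crosses, returns NaN (undefined), not an
    exception.  ``sustain`` requires that many consecutive below-level samples
    before a crossing counts (>1 rejects single-sample noise excursions; the
    interpolated time still uses the first below-level sample).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if sustain < 1:
        raise ValueError("sustain must be >= 1")
    start = series[0]
    total_loss = start - series[-1]
    if threshold is None:
        if total_loss <= 0:
            return float("nan")
        threshold = 0.5 * total_loss
    level = start - threshold
    below = series < level
    for j in range(len(series) - sustain + 1):
        if below[j:j + sustain].all():
            if j == 0:
                return float(times[0])
            t0, t1 = times[j - 1], times[j]
            v0, v1 = series[j - 1], series[j]
            return float(t0 + (v0 - level) / (v0 - v1) * (t1 - t0))
    return float("nan")


def align_by_replication_time(matrix: TimeCourseMatrix, track: NucleosomeTrack,
                              bins: Union[int, Sequence[Tuple[float, float]]] = 4
                              ) -> Tuple[TimeCourseMatrix, pd.DataFrame, List[str]]:
    """Sort rows by annotated replication time (early to late) and average bins.

    ``bins`` is either a number of equal quantile bins or explicit quantile
    intervals (e.g. the non-contiguous ``[(0, .1), (.1, .2), (.8, .9), (.9, 1)]``
    decile selection).  Ties in replication time break by nucleosome id.
    Rows absent from the track are dropped and reported.
    """
    joined = join(matrix, track)
    rt = joined.track.annotation("replication_time_min")
    order = sorted(joined.matrix.ids, key=lambda rid: (rt[rid], rid))
    idx = [joined.matrix.ids.index(rid) for rid in order]
    sorted_matrix = joined.matrix.copy_with(
        ids=order, values=joined.matrix.values[idx])

    if isinstance(bins, int):
        edges = np.linspace(0, 1, bins + 1)
        intervals = list(zip(edges[:-1], edges[1:]))
    else:
        intervals = list(bins)
    n = len(order)
    ranks = np.arange(n) / max(n - 1, 1)
    profiles = []
    for lo, hi in intervals:
        sel = (ranks >= lo) & ((ranks <= hi) if hi >= 1.0 else (ranks < hi))
        profiles.append(np.nanmean(sorted_matrix.values[sel], axis=0))
    bin_profiles = pd.DataFrame(
        profiles, columns=sorted_matrix.times,
        index=[f"q{lo:.2f}-{hi:.2f}" for lo, hi in intervals])
    return sorted_matrix, bin_profiles, joined.dropped_ids


def erasure_fraction(series: np.ndarray, times: np.ndarray, horizon: float,
                     arrest_value: Optional[float] = None) -> float:
    """E(h) = (arrest_value - value(h)) / arrest_value on a baseline-differenced
    series; NaN (reported undefined) when the arrest value is <= 0."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if arrest_value is None:
        arrest_value = float(series[0])
    if arrest_value <= 0:
        return float("nan")
    v_h = float(np.interp(horizon, times, series))
    return (arrest_value - v_h) / arrest_value


def panel_erasure_fraction(matrix: TimeCourseMatrix, horizon: float) -> float:
    """Aggregate erasure fraction: E(h) of the panel-mean profile.

    Averaging before forming the ratio avoids the heavy-tailed per-locus
    ratios that near-zero noisy arrest values produce.
    """
    mean_profile = np.nanmean(matrix.values, axis=0)
    return erasure_fraction(mean_profile, matrix.times, horizon)


def per_locus_erasure(matrix: TimeCourseMatrix, horizon: float) -> pd.Series:
    vals = [erasure_fraction(row, matrix.times, horizon) for row in matrix.values]
    return pd.Series(vals, index=matrix.ids, name=f"erasure@{horizon:g}")


@dataclass
class ReplicationContribution:
    percent_decrease: float      # 100 * (1 - mean(E_norep) / mean(E_rep))
    residual_ratio_percent: float  # 100 * mean(E_norep) / mean(E_rep)
    mean_erasure_rep: float
    mean_erasure_norep: float


def replication_contribution(e_rep: Union[float, Sequence[float]],
                             e_norep: Union[float, Sequence[float]]
                             ) -> ReplicationContribution:
    """Percent decrease in panel erasure when replication is blocked.

    Accepts paired per-locus arrays (NaNs dropped pairwise) or the two
    aggregate panel fractions directly.
    """
    e_rep = np.atleast_1d(np.asarray(e_rep, dtype=float))
    e_norep = np.atleast_1d(np.asarray(e_norep, dtype=float))
    if e_rep.shape != e_norep.shape:
        raise MatrixValidationError("paired panels must have equal size")
    ok = np.isfinite(e_rep) & np.isfinite(e_norep)
    m_rep = float(np.mean(e_rep[ok]))
    m_norep = float(np.mean(e_norep[ok]))
    if m_rep <= 0:
        raise MatrixValidationError(
            "mean replication-enabled erasure is <= 0; contribution undefined")
    ratio = m_norep / m_rep
    return ReplicationContribution(
        percent_decrease=100.0 * (1.0 - ratio),
        residual_ratio_percent=100.0 * ratio,
        mean_erasure_rep=m_rep,
        mean_erasure_norep=m_norep,
    )


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray
    center: float               # arithmetic mean of the finite inputs
    n: int


def difference_histogram(matrix: TimeCourseMatrix, time_point: float,
                         bin_width: float = 0.1) -> Histogram:
    """Histogram of baseline differences at one time point, plus the
    distribution mean ("center")."""
    times = np.asarray(matrix.times, dtype=float)
    matches = np.where(np.isclose(times, time_point))[0]
    if len(matches) == 0:
        raise MatrixValidationError(
            f"time point {time_point} not on the grid {times[0]}..{times[-1]}")
    col = matrix.values[:, matches[0]]
    col = col[np.isfinite(col)]
    if len(col) == 0:
        raise MatrixValidationError("no finite values at the requested time point")
    lo = np.floor(col.min() / bin_width) * bin_width
    hi = np.ceil(col.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(col, bins=edges)
    return Histogram(edges=edges, counts=counts, center=float(col.mean()),
                     n=int(len(col)))
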