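"""Row centering, course concatenation, and differencing against a midlog baseline.

Clustering operates on zero-centered profiles (relative variation); absolute
comparisons against the midlog baseline must use *uncentered* values, and
:func:`difference_to_baseline` enforces that by rejecting centered input.
Missing cells propagate as missing (means are taken over observed cells).
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import MatrixValidationError
from .track_io import TimeCourseMatrix


def zero_center_rows(matrix: TimeCourseMatrix) -> TimeCourseMatrix:
    """Subtract each row's mean within each concatenation segment.

    Idempotent; raises on rows with no observed value in a segment.
    """
    values = matrix.values.copy()
    for lo, hi in matrix.iter_segments():
        block = values[:, lo:hi]
        n_obs = np.sum(np.isfinite(block), axis=1)
        if np.any(n_obs == 0):
            bad = [matrix.ids[i] for i in np.where(n_obs == 0)[0][:5]]
            raise MatrixValidationError(f"all-missing segment for rows {bad}")
        with np.errstate(invalid="ignore"):
            block -= np.nanmean(block, axis=1, keepdims=True)
        values[:, lo:hi] = block
    return matrix.copy_with(values=values, centered=True)


def concatenate_courses(m_a: TimeCourseMatrix, m_b: TimeCourseMatrix
                        ) -> TimeCourseMatrix:
    """Column-wise concatenation of two courses over the same nucleosomes.

    Row order follows ``m_a``; a segment boundary is recorded at the junction.
    Each segment keeps its own clock (times restart at the junction), which the
    segment bookkeeping makes explicit for all downstream per-segment ops.
    """
    if set(m_a.ids) != set(m_b.ids):
        only_a = sorted(set(m_a.ids) - set(m_b.ids))[:5]
        only_b = sorted(set(m_b.ids) - set(m_a.ids))[:5]
        raise MatrixValidationError(
            f"row id sets differ (only in A: {only_a}, only in B: {only_b})")
    order = [m_b.ids.index(rid) for rid in m_a.ids]
    values = np.hstack([m_a.values, m_b.values[order]])
    times = np.concatenate([m_a.times, m_b.times])
    segments = list(m_a.segments) + [s + len(m_a.times) for s in m_b.segments]
    return TimeCourseMatrix(
        ids=list(m_a.ids), times=times, values=values,
        condition=f"{m_a.condition}+{m_b.condition}", channel=m_a.channel,
        centered=m_a.centered and m_b.centered, segments=segments)


def difference_to_baseline(matrix: TimeCourseMatrix,
                           baseline: Union[pd.Series, Mapping[str, float]]
                           ) -> TimeCourseMatrix:
    """Per-cell ``value - baseline[id]``; positive means above midlog.

    Requires uncentered input (centering destroys the absolute scale that a
    baseline comparison needs) and a baseline value for every row id.
    """
    if matrix.centered:
        raise MatrixValidationError(
            "difference_to_baseline requires uncentered values")
    base = pd.Series(baseline)
    missing = [rid for rid in matrix.ids if rid not in base.index]
    if missing:
        raise MatrixValidationError(f"baseline missing ids: {missing[:5]}")
    offsets = base.loc[matrix.ids].to_numpy(dtype=float)[:, None]
    return matrix.copy_with(values=matrix.values - offsets,
                            condition=matrix.condition + "-vs-midlog")
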