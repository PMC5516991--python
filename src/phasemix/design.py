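"""Design matrices for mono- and bi-phasic piecewise-linear regression.

A mono-phasic subject follows one straight line, so its design is the usual
intercept-plus-time matrix.  A bi-phasic subject with change point after its
k-th observation follows two lines: rows 1..k load on the first-phase
intercept/slope, rows k+1..M on the second-phase pair.  A transition before
the first or after the last observation is inadmissible (the two classes
would be indistinguishable), so k ranges over 1..M-1 and a subject with M
observations has exactly M-1 candidate bi-phasic designs.
"""

from __future__ import annotations

import numpy as np

from .data import PatientSeries
from .exceptions import InvalidSeriesError

__all__ = [
    "build_mono_design",
    "build_biphasic_design",
    "enumerate_biphasic_designs",
]


def build_mono_design(times) -> np.ndarray:
    """M x 2 design: a column of ones and the visit times."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise InvalidSeriesError("need at least 2 visit times")
    if not np.all(np.isfinite(times)) or np.any(np.diff(times) <= 0):
        raise InvalidSeriesError("times must be finite and strictly increasing")
    return np.column_stack([np.ones_like(times), times])


def build_biphasic_design(times, k: int) -> np.ndarray:
    """M x 4 block design with k observations in the first phase.

    Rows 1..k are (1, t, 0, 0); rows k+1..M are (0, 0, 1, t).
    """
    times = np.asarray(times, dtype=float)
    m = len(times)
    if m < 2:
        raise InvalidSeriesError("need at least 2 visit times")
    if not (1 <= k <= m - 1):
        raise ValueError(
            f"first-phase count k={k} out of range [1, {m - 1}]: a phasic "
            "transition before the first or after the last observation is "
            "not identifiable"
        )
    q = np.zeros((m, 4))
    q[:k, 0] = 1.0
    q[:k, 1] = times[:k]
    q[k:, 2] = 1.0
    q[k:, 3] = times[k:]
    return q


def enumerate_biphasic_designs(series: PatientSeries) -> list[np.ndarray]:
    """All M-1 candidate bi-phasic designs, ordered k = 1..M-1."""
    return [build_biphasic_design(series.times, k)
            for k in range(1, series.n_obs)]
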