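"""Thrombogram parameters.

Reduces a total-active-thrombin trace sampled on a uniform grid to the six
parameters used for group comparison: maximum level (MaxL, nM) and maximum
rate (MaxR, nM/s) with their times (TMaxL, TMaxR, s), area under the curve
(AUC, µM·s) and clot time (CT, s) — the time at which the trace first reaches
10 nM thrombin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ThrombinMetrics", "compute_metrics", "exceeds_control", "CT_NOT_REACHED"]

#: sentinel for a trace that never reaches the clot-time threshold
CT_NOT_REACHED = math.nan


@dataclass(frozen=True)
class ThrombinMetrics:
    max_level_nM: float
    t_max_level_s: float
    max_rate_nM_s: float
    t_max_rate_s: float
    auc_uM_s: float
    clot_time_s: float  # NaN when the threshold is never reached

    @property
    def ct_reached(self) -> bool:
        return not math.isnan(self.clot_time_s)


def compute_metrics(
    time: np.ndarray,
    trace: np.ndarray,
    ct_threshold_nM: float = 10.0,
    *,
    interpolate_ct: bool = True,
) -> ThrombinMetrics:
    """Compute the six thrombogram parameters from a uniformly sampled trace.

    MaxR is the maximum forward-difference rate on the reporting grid, with
    TMaxR the left endpoint of the maximizing interval; AUC is the trapezoidal
    integral over the full window; CT is the linearly interpolated first
    upward crossing of ``ct_threshold_nM`` (or the first grid sample at or
    above it when ``interpolate_ct=False``).  All ties break to earliest time.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if time.ndim != 1 or time.size < 2 or trace.shape != time.shape:
        raise ValueError("need matching 1-D time and trace arrays with >= 2 samples")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains NaN/Inf")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("non-uniform time grid")
    dt = dt[0]

    def earliest_max(values: np.ndarray) -> tuple[int, float]:
        # earliest index attaining the maximum, tolerant of float noise in ties
        m = float(values.max())
        tol = 1e-9 * max(abs(m), 1e-300)
        return int(np.argmax(values >= m - tol)), m

    i_max, max_level = earliest_max(trace)
    t_max_level = float(time[i_max])

    rates = np.diff(trace) / dt
    i_rate, max_rate = earliest_max(rates)
    t_max_rate = float(time[i_rate])

    auc = float(np.trapezoid(trace, time)) / 1000.0  # nM·s -> µM·s

    ct = CT_NOT_REACHED
    above = trace >= ct_threshold_nM
    if above.any():
        i = int(np.argmax(above))
        if i == 0 or not interpolate_ct:
            ct = float(time[i])
        else:
            y0, y1 = trace[i - 1], trace[i]
            ct = float(time[i - 1] + dt * (ct_threshold_nM - y0) / (y1 - y0))
    return ThrombinMetrics(max_level, t_max_level, max_rate, t_max_rate, auc, ct)


def exceeds_control(metrics: ThrombinMetrics, control: ThrombinMetrics) -> dict[str, bool]:
    """Per-parameter 'more procoagulant than control' flags.

    MaxL/MaxR/AUC exceed when strictly greater; CT exceeds when strictly
    shorter.  A never-reached CT never exceeds; against a never-reached
    control CT, any reached CT exceeds.
    """
    ct_flag = False
    if metrics.ct_reached:
        ct_flag = (not control.ct_reached) or metrics.clot_time_s < control.clot_time_s
    return {
        "MaxL": metrics.max_level_nM > control.max_level_nM,
        "MaxR": metrics.max_rate_nM_s > control.max_rate_nM_s,
        "AUC": metrics.auc_uM_s > control.auc_uM_s,
        "CT": ct_flag,
    }
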