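"""Rate extraction from ThT fluorescence traces.

Two observables carry the mechanistic analysis: the initial slope of a
strongly seeded (elongation-only) trace, and the maximum growth rate of
a sigmoidal (secondary-nucleation) trace.  Both are plain signal
statistics — no kinetic model is assumed here — so they apply equally to
measured plate-reader data and to simulator output.

Times are stored internally in hours; ``time_s`` columns are converted
on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import linregress

__all__ = [
    "ObservedTrace",
    "RateEstimate",
    "TraceError",
    "fit_initial_slope",
    "max_rate",
    "normalize_trace",
    "relative_rates",
    "read_plate_csv",
]


class TraceError(ValueError):
    """A trace does not support the requested analysis."""


@dataclass(frozen=True)
class ObservedTrace:
    """A ThT time course: time (h, strictly increasing) vs signal (a.u.)."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and signal must be matching 1-D arrays")
        if len(t) < 20:
            raise ValueError("a trace needs at least 20 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class RateEstimate:
    """A rate (signal units / h) with the window it was measured in."""

    value: float
    window: tuple
    standard_error: float
    method: str
    flagged: bool = False


def fit_initial_slope(
    trace: ObservedTrace,
    window: "tuple[float, float] | float" = 0.2,
) -> RateEstimate:
    """Ordinary least-squares slope over the early, linear part of a trace.

    ``window`` is either an explicit ``(t0, t1)`` interval (h) or an
    amplitude fraction: points before the signal first exceeds
    baseline + fraction × total amplitude are used (default 20%).
    """
    t, y = trace.time, trace.signal
    if isinstance(window, tuple):
        mask = (t >= window[0]) & (t <= window[1])
    else:
        baseline = y[: max(3, len(y) // 20)].mean()
        cutoff = baseline + window * (y.max() - baseline)
        above = np.nonzero(y > cutoff)[0]
        end = above[0] if len(above) else len(y)
        mask = np.zeros(len(t), dtype=bool)
        mask[: max(end, 0)] = True
    if mask.sum() < 5:
        raise TraceError("initial-slope window contains fewer than 5 points")
    res = linregress(t[mask], y[mask])
    return RateEstimate(
        value=float(res.slope),
        window=(float(t[mask][0]), float(t[mask][-1])),
        standard_error=float(res.stderr),
        method="initial_slope",
    )


def max_rate(trace: ObservedTrace, smoothing_halfwidth: int = 5) -> RateEstimate:
    """Maximum first derivative by Savitzky-Golay local-polynomial differentiation.

    The window is ``2*smoothing_halfwidth + 1`` points and the local
    polynomial is quadratic.  A non-uniform time grid is interpolated to
    uniform spacing first.  If the maximum rate does not exceed three
    times the derivative-noise level, the estimate is flagged.
    """
    t, y = trace.time, trace.signal
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6 * dt.mean():
        n = len(t)
        tu = np.linspace(t[0], t[-1], n)
        y = np.interp(tu, t, y)
        t = tu
        dt = np.diff(t)
    window = 2 * int(smoothing_halfwidth) + 1
    if window >= len(t):
        raise TraceError("smoothing window exceeds trace length")
    deriv = savgol_filter(y, window, polyorder=2, deriv=1, delta=float(dt[0]))
    i = int(np.argmax(deriv))
    # derivative noise from the high-frequency residual of the smoothing fit
    resid = y - savgol_filter(y, window, polyorder=2)
    sigma = float(np.std(resid))
    m = smoothing_halfwidth
    # variance of the slope of a local quadratic ≈ that of a local line
    denom = float(dt[0]) * np.sqrt(m * (m + 1) * (2 * m + 1) / 3.0)
    se = 3.0 * sigma / denom if denom > 0 else np.inf
    value = float(deriv[i])
    return RateEstimate(
        value=value,
        window=(float(t[max(0, i - m)]), float(t[min(len(t) - 1, i + m)])),
        standard_error=se,
        method="max_rate",
        flagged=bool(value < 3.0 * se),
    )


def normalize_trace(
    trace: ObservedTrace, plateau_tolerance: float = 0.05
) -> ObservedTrace:
    """Map the baseline to 0 and the plateau to 1.

    Baseline is the mean of the first 5% of points, plateau the mean of
    the last 10%.  The trace must have reached a plateau: the final 10%
    may vary by at most ``plateau_tolerance`` of the total amplitude.
    """
    t, y = trace.time, trace.signal
    n = len(y)
    baseline = y[: max(2, n // 20)].mean()
    tail = y[-max(2, n // 10):]
    plateau = tail.mean()
    amplitude = plateau - baseline
    if abs(amplitude) <= 1e-12 * max(1.0, abs(plateau)):
        raise TraceError("flat trace: no plateau above baseline; analyse raw rates instead")
    if np.ptp(tail) > plateau_tolerance * abs(amplitude):
        raise TraceError("no plateau reached; analyse raw rates instead")
    return ObservedTrace(t, (y - baseline) / amplitude, dict(trace.metadata))


def relative_rates(
    estimates: "dict[object, list[RateEstimate]]", reference: object
) -> pd.DataFrame:
    """Per-condition rates relative to a reference condition.

    ``estimates`` maps a condition label (e.g. inhibitor concentration)
    to its replicate :class:`RateEstimate` list.  Each condition mean is
    divided by the reference mean; errors combine replicate scatter (SEM,
    when there are replicates) with the fit standard errors, propagated
    to the ratio at first order.
    """
    if reference not in estimates:
        raise ValueError(f"reference condition {reference!r} not present")

    def summarize(items: "list[RateEstimate]"):
        vals = np.array([e.value for e in items], dtype=float)
        fit_se = np.array([e.standard_error for e in items], dtype=float)
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        prop = np.sqrt(np.sum(fit_se**2)) / len(fit_se)
        return mean, float(np.hypot(sem, prop))

    ref_mean, ref_se = summarize(estimates[reference])
    if ref_mean == 0:
        raise ValueError("reference mean rate is zero")
    rows = []
    for cond, items in estimates.items():
        mean, se = summarize(items)
        ratio = mean / ref_mean
        err = abs(ratio) * np.hypot(se / mean if mean else np.inf, ref_se / ref_mean)
        rows.append({"condition": cond, "n": len(items), "mean_rate": mean,
                     "relative_rate": ratio, "relative_rate_se": err})
    return pd.DataFrame(rows)


def read_plate_csv(path, condition_map=None) -> "list[ObservedTrace]":
    """Read a plate-reader export: ``time_s`` (or ``time_h``) plus one column per well.

    ``condition_map`` is an optional CSV path or DataFrame with columns
    ``well, inhibitor_uM, replicate`` merged into each trace's metadata.
    """
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        time = df.pop("time_s").to_numpy() / 3600.0
    elif "time_h" in df.columns:
        time = df.pop("time_h").to_numpy()
    else:
        raise ValueError("plate CSV needs a 'time_s' or 'time_h' column")
    cond = None
    if condition_map is not None:
        cond = (
            condition_map
            if isinstance(condition_map, pd.DataFrame)
            else pd.read_csv(condition_map)
        ).set_index("well")
    traces = []
    for well in df.columns:
        meta = {"well": well}
        if cond is not None and well in cond.index:
            meta.update(cond.loc[well].to_dict())
        traces.append(ObservedTrace(time, df[well].to_numpy(), meta))
    return traces
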