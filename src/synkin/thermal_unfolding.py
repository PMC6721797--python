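"""Two-state thermal unfolding of CD melting curves.

The observable is the CD signal at 222 nm as a function of temperature.
Folded and unfolded states each contribute a linear baseline, and the
equilibrium between them follows a van 't Hoff law with midpoint ``t_m``
and enthalpy ``delta_h_m`` (ΔCp fixed at zero):

    y(T) = [ (yf + mf*T) + (yu + mu*T) * K(T) ] / (1 + K(T))
    K(T) = exp( (ΔHm / (R*T)) * (T - Tm) / Tm )

Temperatures are Kelvin internally; Celsius is accepted and reported at
the interfaces (CSV columns, fit reports) since melting points are
conventionally quoted in °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "R_J_PER_MOL_K",
    "CELSIUS_OFFSET",
    "MeltingCurve",
    "TwoStateParams",
    "FitError",
    "eval_two_state",
    "fraction_unfolded",
    "fit_two_state",
]

R_J_PER_MOL_K = 8.314
CELSIUS_OFFSET = 273.15


class FitError(RuntimeError):
    """Least-squares fit failed or is unidentifiable."""


@dataclass(frozen=True)
class TwoStateParams:
    """Baselines and thermodynamics of a two-state melt.

    ``delta_h_m`` is in kJ/mol, ``t_m`` in Kelvin; the baselines are in
    mdeg and mdeg/K.  ``stderr`` (optional) maps field names to standard
    errors from the fit covariance.
    """

    y_folded_intercept: float
    y_folded_slope: float
    y_unfolded_intercept: float
    y_unfolded_slope: float
    delta_h_m: float
    t_m: float
    stderr: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.t_m <= 0:
            raise ValueError("t_m must be positive (Kelvin)")

    @property
    def t_m_celsius(self) -> float:
        return self.t_m - CELSIUS_OFFSET


@dataclass(frozen=True)
class MeltingCurve:
    """Temperature (K, strictly increasing) vs CD signal (mdeg)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("temperature and signal must be matching 1-D arrays")
        if len(t) < 10:
            raise ValueError("a melting curve needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("temperatures and signals must be finite")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)

    @classmethod
    def from_celsius(cls, temperature_c, signal) -> "MeltingCurve":
        return cls(np.asarray(temperature_c, dtype=float) + CELSIUS_OFFSET, signal)


def _equilibrium_constant(delta_h_m: float, t_m: float, temperature):
    t = np.asarray(temperature, dtype=float)
    return np.exp(delta_h_m * 1e3 / (R_J_PER_MOL_K * t) * (t - t_m) / t_m)


def eval_two_state(params: TwoStateParams, temperature):
    """CD signal (mdeg) of the two-state model at the given temperature(s) in K."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    k = _equilibrium_constant(params.delta_h_m, params.t_m, t)
    folded = params.y_folded_intercept + params.y_folded_slope * t
    unfolded = params.y_unfolded_intercept + params.y_unfolded_slope * t
    out = (folded + unfolded * k) / (1.0 + k)
    return out if out.ndim else float(out)


def fraction_unfolded(params: TwoStateParams, temperature):
    """Unfolded population K/(1+K); exactly 0.5 at T = Tm."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    k = _equilibrium_constant(params.delta_h_m, params.t_m, t)
    out = k / (1.0 + k)
    return out if out.ndim else float(out)


def _model(t, yf, mf, yu, mu, dhm, tm):
    k = np.exp(dhm * 1e3 / (R_J_PER_MOL_K * t) * (t - tm) / tm)
    return (yf + mf * t + (yu + mu * t) * k) / (1.0 + k)


def _auto_initial(curve: MeltingCurve) -> TwoStateParams:
    """Initial guess: baselines from the outer 10% of points, Tm from the
    midpoint crossing, ΔHm from the local slope at the midpoint."""
    t, y = curve.temperature, curve.signal
    n = len(t)
    k = max(3, n // 10)
    pf = np.polyfit(t[:k], y[:k], 1)
    pu = np.polyfit(t[-k:], y[-k:], 1)
    mid = 0.5 * (np.polyval(pf, t) + np.polyval(pu, t))
    cross = np.nonzero(np.diff(np.sign(y - mid)))[0]
    i = cross[0] if len(cross) else n // 2
    tm0 = float(t[i])
    # dy/dT at midpoint ≈ (yu-yf)(Tm) * ΔHm / (4 R Tm^2)
    span = np.polyval(pu, tm0) - np.polyval(pf, tm0)
    window = slice(max(0, i - 2), min(n, i + 3))
    slope = np.polyfit(t[window], y[window], 1)[0]
    if span != 0 and np.isfinite(slope):
        dhm0 = abs(4.0 * R_J_PER_MOL_K * tm0**2 * slope / span) / 1e3
        dhm0 = float(np.clip(dhm0, 20.0, 2000.0))
    else:
        dhm0 = 300.0
    return TwoStateParams(pf[1], pf[0], pu[1], pu[0], dhm0, tm0)


def fit_two_state(curve: MeltingCurve, initial: TwoStateParams | None = None) -> TwoStateParams:
    """Least-squares fit of the two-state model to a melting curve.

    Returns the fitted parameters with standard errors from the fit
    covariance.  Raises :class:`FitError` on non-convergence and warns if
    the fitted midpoint lies outside the measured temperature span.
    """
    t, y = curve.temperature, curve.signal
    noise_floor = np.std(np.diff(y)) / np.sqrt(2.0)
    if np.ptp(y) <= 3.0 * max(noise_floor, 1e-12):
        raise FitError("signal range does not exceed the noise floor; no transition to fit")
    p = initial if initial is not None else _auto_initial(curve)
    p0 = [
        p.y_folded_intercept,
        p.y_folded_slope,
        p.y_unfolded_intercept,
        p.y_unfolded_slope,
        p.delta_h_m,
        p.t_m,
    ]
    try:
        popt, pcov = curve_fit(_model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"two-state fit did not converge: {exc}") from exc
    resid0 = float(np.linalg.norm(y - _model(t, *p0)))
    resid = float(np.linalg.norm(y - _model(t, *popt)))
    if resid > resid0 * (1.0 + 1e-9):
        raise FitError("fit residual exceeds that of the initial guess")
    if not (t[0] <= popt[5] <= t[-1]):
        import warnings

        warnings.warn("fitted melting midpoint lies outside the measured span", stacklevel=2)
    perr = np.sqrt(np.diag(pcov))
    names = [
        "y_folded_intercept",
        "y_folded_slope",
        "y_unfolded_intercept",
        "y_unfolded_slope",
        "delta_h_m",
        "t_m",
    ]
    return TwoStateParams(*popt, stderr=dict(zip(names, perr)))
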