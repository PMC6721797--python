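"""Coupled binding equilibria for α-synuclein sequestration.

Two systems are solved here:

* the 1:1 equilibrium between monomeric α-synuclein and the engineered
  β-wrapin AS69 (a disulfide-linked dimer treated as a single binding
  entity with one site), and
* the three-species competition in which AS69 and DMPS lipid vesicles
  both bind monomeric α-synuclein.  Lipid binding is mass-action with a
  stoichiometry ``l_alpha`` — the number of lipid molecules engaged per
  bound α-synuclein.

All concentrations are in µM at module boundaries.  The competitive
system is solved by safeguarded 1-D root finding on free α-synuclein
(every other species has a closed form given the free monomer), which is
numerically robust over the full parameter range, including the limits
in which one competitor vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "OneToOneSystem",
    "CompetitiveLipidSystem",
    "Speciation",
    "EquilibriumError",
    "DegenerateCalibrationError",
    "solve_one_to_one",
    "solve_competitive",
    "cd_fraction_bound",
    "predict_cd_titration",
]

#: default absolute tolerance on mass-balance residuals, µM
RESIDUAL_TOL = 1e-10


class EquilibriumError(RuntimeError):
    """Equilibrium solver failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateCalibrationError(ValueError):
    """CD calibration signals for free and bound states coincide."""


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


def _check_pos(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class OneToOneSystem:
    """A 1:1 binding system: total monomer, total binder, dissociation constant (µM)."""

    monomer_total: float
    binder_total: float
    kd: float

    def __post_init__(self) -> None:
        _check_nonneg(monomer_total=self.monomer_total, binder_total=self.binder_total)
        _check_pos(kd=self.kd)


@dataclass(frozen=True)
class CompetitiveLipidSystem:
    """AS69 and DMPS vesicles competing for monomeric α-synuclein.

    ``dmps_total`` counts lipid molecules; ``l_alpha`` lipids are engaged
    per lipid-bound α-synuclein.
    """

    alpha_total: float
    as69_total: float
    dmps_total: float
    kd_alpha_dmps: float
    kd_alpha_as69: float
    l_alpha: float

    def __post_init__(self) -> None:
        _check_nonneg(
            alpha_total=self.alpha_total,
            as69_total=self.as69_total,
            dmps_total=self.dmps_total,
        )
        _check_pos(kd_alpha_dmps=self.kd_alpha_dmps, kd_alpha_as69=self.kd_alpha_as69)
        if self.l_alpha < 1:
            raise ValueError(f"l_alpha must be >= 1, got {self.l_alpha!r}")


@dataclass
class Speciation:
    """Equilibrium concentrations of every species (µM) plus the residual.

    ``residual`` is the largest absolute mass-balance violation, in µM.
    """

    alpha_free: float
    alpha_lipid_bound: float
    alpha_as69_bound: float
    as69_free: float
    dmps_free: float
    residual: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def solve_one_to_one(system: OneToOneSystem) -> Speciation:
    """Solve the 1:1 mass-action equilibrium exactly.

    The complex concentration is the physically admissible root of

        c**2 - (m_t + b_t + Kd) c + m_t b_t = 0,

    evaluated in the numerically stable form ``2 m_t b_t / (s + sqrt(s**2
    - 4 m_t b_t))`` with ``s = m_t + b_t + Kd``, which avoids cancellation
    when binding is weak.
    """
    mt, bt, kd = system.monomer_total, system.binder_total, system.kd
    if mt == 0.0 or bt == 0.0:
        return Speciation(mt, 0.0, 0.0, bt, 0.0, residual=0.0)
    s = mt + bt + kd
    disc = s * s - 4.0 * mt * bt
    c = 2.0 * mt * bt / (s + np.sqrt(disc))
    c = min(c, mt, bt)  # guard rounding at the tight-binding limit
    resid = max(abs(kd * c - (mt - c) * (bt - c)) / max(s, 1.0), 0.0)
    return Speciation(mt - c, 0.0, c, bt - c, 0.0, residual=resid)


def _competitive_species(af: float, system: CompetitiveLipidSystem):
    """Closed forms for the bound pools given free α-synuclein ``af``."""
    ab = system.dmps_total * af / (system.l_alpha * (system.kd_alpha_dmps + af))
    cb = system.as69_total * af / (system.kd_alpha_as69 + af)
    return ab, cb


def solve_competitive(system: CompetitiveLipidSystem, tol: float = RESIDUAL_TOL) -> Speciation:
    """Solve the three-species AS69 / DMPS / α-synuclein competition.

    Both bound pools are monotone increasing functions of the free
    monomer, so the α-synuclein mass balance has a single root in
    ``[0, alpha_total]`` which is bracketed and found by Brent's method.
    """
    at = system.alpha_total
    if at == 0.0:
        return Speciation(0.0, 0.0, 0.0, system.as69_total, system.dmps_total, 0.0)

    def balance(af: float) -> float:
        ab, cb = _competitive_species(af, system)
        return af + ab + cb - at

    try:
        af = brentq(balance, 0.0, at, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise EquilibriumError(f"competitive solve failed: {exc}") from exc

    ab, cb = _competitive_species(af, system)
    dmps_free = system.dmps_total - system.l_alpha * ab
    as69_free = system.as69_total - cb
    residual = max(
        abs(af + ab + cb - at),
        abs(dmps_free + system.l_alpha * ab - system.dmps_total),
        abs(as69_free + cb - system.as69_total),
    )
    scale = max(at, system.as69_total, system.dmps_total, 1.0)
    if residual > max(tol, 1e-12 * scale):
        raise EquilibriumError(
            f"competitive solve residual {residual:.3e} µM exceeds tolerance", residual
        )
    return Speciation(af, ab, cb, as69_free, dmps_free, residual)


def cd_fraction_bound(cd_measured: float, cd_free: float, cd_bound: float) -> float:
    """Fraction of α-synuclein bound to lipid from a CD signal.

    Linear interpolation between the calibration signals of the free and
    the lipid-saturated protein.  Noisy data can land slightly outside
    [0, 1]; such values are returned as-is with a warning rather than
    clipped, so that downstream fits see the data faithfully.
    """
    if cd_bound == cd_free:
        raise DegenerateCalibrationError(
            "cd_bound equals cd_free: calibration cannot resolve binding"
        )
    xb = (cd_measured - cd_free) / (cd_bound - cd_free)
    if xb < 0.0 or xb > 1.0:
        warnings.warn(
            f"fraction bound {xb:.4f} outside [0, 1]; reported unclipped",
            stacklevel=2,
        )
    return xb


def predict_cd_titration(
    system: CompetitiveLipidSystem, dmps_grid: "np.ndarray | list[float]"
) -> np.ndarray:
    """Predicted lipid-bound fraction x_b over an ascending DMPS grid.

    Each grid point replaces ``dmps_total`` in the template system; x_b is
    ``alpha_lipid_bound / alpha_total`` from the competitive solve.
    """
    grid = np.asarray(dmps_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("dmps_grid must be a non-empty 1-D sequence")
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("dmps_grid must be non-negative and ascending")
    if system.alpha_total == 0:
        raise ValueError("alpha_total must be positive for a titration")
    xb = np.empty_like(grid)
    for i, d in enumerate(grid):
        spec = solve_competitive(
            CompetitiveLipidSystem(
                system.alpha_total,
                system.as69_total,
                float(d),
                system.kd_alpha_dmps,
                system.kd_alpha_as69,
                system.l_alpha,
            )
        )
        xb[i] = spec.alpha_lipid_bound / system.alpha_total
    return xb
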