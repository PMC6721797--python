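"""Kinetic models of α-synuclein fibril formation under monomer sequestration.

Three experimental regimes are modelled:

* **Seeded elongation** (strong seeding, neutral pH, quiescent): only
  fibril growth occurs.  A monomer-sequestering inhibitor slows growth
  exactly in proportion to the free-monomer fraction, so the prediction
  is algebraic — no ODE needed.
* **Secondary nucleation** (weak seeding, mildly acidic pH): fibril mass
  M grows by elongation while fibril number P is amplified
  autocatalytically on fibril surfaces with reaction order ``n2`` in the
  free monomer,

      dP/dt = k2 * m^n2 * M,      dM/dt = 2 * k_plus * m * P.

* **Lipid-induced nucleation**: new fibrils nucleate from lipid-bound
  monomer on DMPS vesicles (one-step nucleation, order ``nc``), and grow
  from free monomer,

      dP/dt = kn * b^nc,          dM/dt = 2 * k_plus * f * P.

In every simulator the inhibitor acts solely by sequestering monomer:
binding equilibrates much faster than aggregation, so at each instant
the free monomer is the equilibrium value for the current unaggregated
pool (an algebraic constraint inside the ODE right-hand side).  The
factor 2 in dM/dt (two growing ends per fibril) is a convention that
cancels in every relative rate.

Primary nucleation, fragmentation and higher-order assembly are omitted:
under the quiescent, non-binding-surface conditions modelled here they
do not contribute measurably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import (
    CompetitiveLipidSystem,
    OneToOneSystem,
    solve_competitive,
    solve_one_to_one,
)

__all__ = [
    "ElongationSetup",
    "SecondaryNucleationModel",
    "LipidNucleationModel",
    "SimulatedTrace",
    "IntegrationError",
    "free_monomer",
    "predict_relative_elongation_rate",
    "simulate_secondary_nucleation",
    "max_mass_rate_secondary",
    "relative_max_rate_curve",
    "simulate_lipid_induced",
    "predict_relative_lipid_rate",
]


class IntegrationError(RuntimeError):
    """ODE integration failed; consider loosening/tightening tolerances."""


@dataclass(frozen=True)
class ElongationSetup:
    """Strongly seeded growth: monomer, seeds, elongation rate, inhibitor."""

    monomer_total: float
    seed_mass: float
    k_plus: float
    as69_total: float = 0.0
    kd: float = 0.24

    def __post_init__(self) -> None:
        if min(self.monomer_total, self.seed_mass, self.k_plus, self.as69_total) < 0:
            raise ValueError("concentrations and rates must be non-negative")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass(frozen=True)
class SecondaryNucleationModel:
    """Elongation + surface-catalysed secondary nucleation with sequestration.

    Units: concentrations µM, time h; ``k2`` in µM^(1-n2)/h, ``k_plus``
    in 1/(µM·h).  ``fibril_number`` counts fibrils (pairs of growing
    ends) in µM.
    """

    monomer_total: float
    fibril_mass_0: float
    fibril_number_0: float
    k_plus: float
    k2: float
    n2: float
    as69_total: float = 0.0
    kd: float = 0.24

    def __post_init__(self) -> None:
        if not 0 <= self.n2 <= 5:
            raise ValueError("reaction orders n2 in [0, 5] are supported")
        if min(
            self.monomer_total,
            self.fibril_mass_0,
            self.fibril_number_0,
            self.k_plus,
            self.k2,
            self.as69_total,
        ) < 0:
            raise ValueError("concentrations and rates must be non-negative")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass(frozen=True)
class LipidNucleationModel:
    """One-step nucleation from lipid-bound monomer plus elongation."""

    system: CompetitiveLipidSystem
    kn: float
    nc: float
    k_plus: float

    def __post_init__(self) -> None:
        if self.kn < 0 or self.k_plus < 0:
            raise ValueError("rate constants must be non-negative")
        if self.nc < 1:
            raise ValueError("nucleation order nc must be >= 1")


@dataclass(frozen=True)
class SimulatedTrace:
    """Time course of fibril mass M, fibril number P and free monomer (µM, h)."""

    time: np.ndarray
    fibril_mass: np.ndarray
    fibril_number: np.ndarray
    free_monomer: np.ndarray

    def mass_rate(self) -> np.ndarray:
        """dM/dt by spline-quality central differences on the stored grid."""
        return np.gradient(self.fibril_mass, self.time)


def free_monomer(unaggregated_total: float, as69_total: float, kd: float) -> float:
    """Equilibrium free monomer when ``as69_total`` sequesters part of the pool."""
    mt = max(unaggregated_total, 0.0)
    if mt == 0.0 or as69_total == 0.0:
        return mt
    return solve_one_to_one(OneToOneSystem(mt, as69_total, kd)).alpha_free


def predict_relative_elongation_rate(setup: ElongationSetup) -> float:
    """Sequestration-only prediction of the relative elongation rate.

    The complex cannot add onto fibril ends, so the initial elongation
    rate scales with the free monomer: the prediction is exactly
    ``alpha_free(as69_total) / alpha_free(0)``.
    """
    if setup.monomer_total == 0:
        return 1.0
    return free_monomer(setup.monomer_total, setup.as69_total, setup.kd) / setup.monomer_total


def _secondary_rhs(model: SecondaryNucleationModel):
    m_tot0 = model.monomer_total + model.fibril_mass_0

    def rhs(t, y):
        p, mass = y
        mf = free_monomer(m_tot0 - mass, model.as69_total, model.kd)
        dp = model.k2 * mf**model.n2 * mass
        dm = 2.0 * model.k_plus * mf * p
        return (dp, dm)

    return rhs, m_tot0


def simulate_secondary_nucleation(
    model: SecondaryNucleationModel,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulatedTrace:
    """Integrate the secondary-nucleation model on an ascending time grid.

    Monomer binding is imposed as an instantaneous equilibrium inside the
    right-hand side (rapid-equilibrium assumption); total protein is
    conserved to integrator tolerance.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be ascending and start at 0")
    rhs, m_tot0 = _secondary_rhs(model)
    sol = solve_ivp(
        rhs,
        (0.0, t[-1]),
        [model.fibril_number_0, model.fibril_mass_0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"secondary-nucleation integration failed: {sol.message}; "
            "try loosening rtol/atol"
        )
    mass = np.minimum(sol.y[1], m_tot0)
    mf = np.array([free_monomer(m_tot0 - m, model.as69_total, model.kd) for m in mass])
    return SimulatedTrace(t, mass, sol.y[0], mf)


def _amplification_rate(model: SecondaryNucleationModel) -> float:
    """κ = sqrt(2 k+ k2 m^(n2+1)) at t=0; the inverse sets the timescale."""
    mf0 = free_monomer(model.monomer_total, model.as69_total, model.kd)
    return float(np.sqrt(2.0 * model.k_plus * model.k2 * mf0 ** (model.n2 + 1.0)))


def max_mass_rate_secondary(model: SecondaryNucleationModel, horizon: float | None = None) -> float:
    """Maximum of dM/dt over the whole reaction, from the model derivative.

    The integration horizon is chosen from the amplification rate and
    extended until aggregation has completed; the rate is evaluated
    analytically (from the rate laws) on the dense solution.
    """
    rhs, m_tot0 = _secondary_rhs(model)
    if model.k2 == 0.0:
        # no amplification: dM/dt is maximal at t = 0, on the unaggregated pool
        mf0 = free_monomer(model.monomer_total, model.as69_total, model.kd)
        return 2.0 * model.k_plus * mf0 * model.fibril_number_0
    kappa = _amplification_rate(model)
    if kappa == 0.0:
        # k_plus or free monomer is zero: fibril mass cannot grow
        return 0.0
    if horizon is None:
        horizon = 60.0 / kappa

    done = lambda t, y: y[1] - 0.999 * m_tot0  # noqa: E731
    done.terminal = True
    done.direction = 1.0
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [model.fibril_number_0, model.fibril_mass_0],
        method="LSODA",
        events=done,
        dense_output=True,
        rtol=1e-9,
        atol=1e-13,
    )
    if not sol.success:
        raise IntegrationError(f"max-rate integration failed: {sol.message}")
    t_end = sol.t[-1]
    tt = np.linspace(0.0, t_end, 4000)
    y = sol.sol(tt)
    rates = np.array([rhs(ti, yi)[1] for ti, yi in zip(tt, y.T)])
    return float(rates.max())


def relative_max_rate_curve(
    model: SecondaryNucleationModel, as69_grid, orders
) -> np.ndarray:
    """Relative maximum aggregation rate vs inhibitor, per reaction order.

    Returns a matrix of shape ``(len(orders), len(as69_grid))`` where each
    entry is max_t dM/dt at that inhibitor concentration divided by the
    uninhibited maximum for the same order.  ``k2`` is rescaled by
    ``monomer_total**(model.n2 - order)`` per order so that uninhibited
    reactions share a comparable timescale; the rescaling cancels in the
    ratio.
    """
    grid = np.asarray(as69_grid, dtype=float)
    if grid.ndim != 1 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("as69_grid must be ascending and include 0 first")
    orders = list(orders)
    out = np.empty((len(orders), len(grid)))
    for i, n2 in enumerate(orders):
        k2 = model.k2 * model.monomer_total ** (model.n2 - n2)
        base = None
        for j, a in enumerate(grid):
            m = SecondaryNucleationModel(
                model.monomer_total,
                model.fibril_mass_0,
                model.fibril_number_0,
                model.k_plus,
                k2,
                n2,
                float(a),
                model.kd,
            )
            r = max_mass_rate_secondary(m)
            if j == 0:
                base = r
            out[i, j] = r / base
    return out


def _lipid_speciation(model: LipidNucleationModel, unaggregated: float):
    sys0 = model.system
    return solve_competitive(
        CompetitiveLipidSystem(
            max(unaggregated, 0.0),
            sys0.as69_total,
            sys0.dmps_total,
            sys0.kd_alpha_dmps,
            sys0.kd_alpha_as69,
            sys0.l_alpha,
        )
    )


def simulate_lipid_induced(
    model: LipidNucleationModel,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulatedTrace:
    """Integrate lipid-induced one-step nucleation plus elongation.

    At each instant the unaggregated monomer pool is partitioned between
    free, AS69-bound and lipid-bound states by the competitive
    equilibrium; nucleation draws on the lipid-bound pool and elongation
    on the free pool.  Early-time fibril mass grows as
    ``kn * k_plus * b0^nc * f0 * t**2``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be ascending and start at 0")
    alpha0 = model.system.alpha_total

    def rhs(_t, y):
        p, mass = y
        spec = _lipid_speciation(model, alpha0 - mass)
        dp = model.kn * spec.alpha_lipid_bound**model.nc
        dm = 2.0 * model.k_plus * spec.alpha_free * p
        return (dp, dm)

    sol = solve_ivp(
        rhs, (0.0, t[-1]), [0.0, 0.0], method="LSODA", t_eval=t, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(f"lipid-induced integration failed: {sol.message}")
    mass = np.minimum(sol.y[1], alpha0)
    mf = np.array([_lipid_speciation(model, alpha0 - m).alpha_free for m in mass])
    return SimulatedTrace(t, mass, sol.y[0], mf)


def predict_relative_lipid_rate(model: LipidNucleationModel, as69_grid) -> np.ndarray:
    """Sequestration-only relative rate of lipid-induced aggregation.

    The early-time fibril mass is quadratic, M(t) ≈ kn·k+·b0^nc·f0·t², so
    the relative rate is the ratio of the quadratic coefficients — a pure
    function of the competitive speciation at t = 0.
    """
    grid = np.asarray(as69_grid, dtype=float)
    if grid.ndim != 1 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("as69_grid must be ascending and include 0 first")
    sys0 = model.system

    def coeff(as69: float) -> float:
        spec = solve_competitive(
            CompetitiveLipidSystem(
                sys0.alpha_total,
                as69,
                sys0.dmps_total,
                sys0.kd_alpha_dmps,
                sys0.kd_alpha_as69,
                sys0.l_alpha,
            )
        )
        return spec.alpha_lipid_bound**model.nc * spec.alpha_free

    base = coeff(0.0)
    if base == 0.0:
        raise ValueError("uninhibited reaction has zero nucleation flux (no lipid-bound monomer)")
    return np.array([coeff(float(a)) / base for a in grid])
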