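"""1:1 binding observables: ITC injection heats and MST dose-response curves.

The ITC forward model follows the standard perfusion-cell bookkeeping:
the cell volume is constant, each injection displaces its own volume of
cell content, so both titrand and titrant in the active volume are
diluted by ``1 - dV/V0`` before the injected titrant is added.  The heat
of injection *i* is the binding enthalpy times the change in moles of
complex inside the cell between injections (displaced complex is
accounted for), plus a constant per-mole-injected dilution heat.

MST dose-response curves are modelled as a linear transform of the
fraction of fluorescent tracer bound.  With ``depletion`` on, the bound
fraction at each titration point comes from the exact 1:1 equilibrium
(:func:`synkin.equilibrium.solve_one_to_one`), so the tracer
concentration is not assumed negligible — essential when the tracer is
comparable to or above the Kd, as with the tight oligomer interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .equilibrium import OneToOneSystem, solve_one_to_one

__all__ = [
    "ITCExperiment",
    "ITCParams",
    "DoseResponseCurve",
    "DoseResponseFit",
    "UnidentifiableFitError",
    "simulate_itc",
    "correct_dilution_heats",
    "fit_itc",
    "fit_dose_response",
    "oligomer_number_concentration",
]


class UnidentifiableFitError(RuntimeError):
    """The data do not constrain the binding parameters."""


@dataclass(frozen=True)
class ITCExperiment:
    """Titration geometry: titrand in the cell, titrant in the syringe.

    Concentrations in µM, volumes in µL, temperature in K.
    """

    cell_concentration: float
    syringe_concentration: float
    cell_volume: float
    injection_volumes: tuple
    temperature: float = 303.15

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if min(self.cell_concentration, self.syringe_concentration, self.cell_volume, self.temperature) <= 0:
            raise ValueError("concentrations, cell volume and temperature must be positive")
        if len(vols) < 5:
            raise ValueError("an ITC experiment needs at least 5 injections")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class ITCParams:
    """1:1 binding parameters: Kd (µM), ΔH (kJ/mol of injectant bound),
    stoichiometry n (binding sites per cell molecule) and a constant
    dilution heat (kJ/mol injected)."""

    kd: float
    delta_h: float
    stoichiometry_n: float = 1.0
    dilution_offset: float = 0.0
    stderr: dict | None = field(default=None, compare=False)
    low_confidence: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.stoichiometry_n <= 0:
            raise ValueError("stoichiometry_n must be positive")


def simulate_itc(params: ITCParams, experiment: ITCExperiment) -> np.ndarray:
    """Per-injection heats (µJ) for a 1:1 titration.

    Sign convention: exothermic binding (ΔH < 0) gives negative heats.
    """
    v0 = experiment.cell_volume
    sites = params.stoichiometry_n * experiment.cell_concentration  # µM of sites
    titrant = 0.0
    heats = np.empty(len(experiment.injection_volumes))
    complex_prev = 0.0
    for i, dv in enumerate(experiment.injection_volumes):
        fd = 1.0 - dv / v0
        sites *= fd
        titrant = titrant * fd + experiment.syringe_concentration * dv / v0
        complex_now = solve_one_to_one(
            OneToOneSystem(titrant, sites, params.kd)
        ).alpha_as69_bound
        # µM * µL = pmol; kJ/mol * pmol = 1e-3 µJ
        d_complex_pmol = (complex_now - complex_prev * fd) * v0
        injected_pmol = experiment.syringe_concentration * dv
        heats[i] = (params.delta_h * d_complex_pmol + params.dilution_offset * injected_pmol) * 1e-3
        complex_prev = complex_now
    return heats


def correct_dilution_heats(heats, n_post_saturation: int) -> np.ndarray:
    """Subtract the mean of the last ``n_post_saturation`` heats from every injection."""
    h = np.asarray(heats, dtype=float)
    if n_post_saturation < 2 or n_post_saturation >= len(h):
        raise ValueError(
            "n_post_saturation must be >= 2 and smaller than the number of injections"
        )
    return h - h[-n_post_saturation:].mean()


def _itc_residual(p: lmfit.Parameters, heats: np.ndarray, experiment: ITCExperiment):
    model = simulate_itc(
        ITCParams(p["kd"].value, p["delta_h"].value, p["stoichiometry_n"].value, p["dilution_offset"].value),
        experiment,
    )
    return model - heats


def fit_itc(
    heats,
    experiment: ITCExperiment,
    initial: ITCParams | None = None,
    fix_stoichiometry: bool = False,
) -> ITCParams:
    """Nonlinear least-squares fit of the 1:1 model to integrated heats.

    The stoichiometry is free by default.  A fit whose relative Kd
    standard error exceeds 100% (the low c-value regime, c = cell
    concentration / Kd < 1) is flagged ``low_confidence``.
    """
    h = np.asarray(heats, dtype=float)
    if len(h) != len(experiment.injection_volumes):
        raise ValueError("number of heats must match number of injections")
    if np.ptp(h) <= 1e-12 * max(1.0, np.abs(h).max(initial=0.0)):
        raise UnidentifiableFitError("flat thermogram: binding parameters unidentifiable")

    if initial is None:
        # total observed heat ≈ ΔH × (sites in cell), assuming near saturation
        site_pmol = experiment.cell_concentration * experiment.cell_volume
        dh0 = float(np.clip(h.sum() * 1e3 / site_pmol, -500.0, 500.0))
        if dh0 == 0.0:
            dh0 = -10.0
        initial = ITCParams(
            kd=max(experiment.cell_concentration / 50.0, 1e-4),
            delta_h=dh0,
            stoichiometry_n=1.0,
            dilution_offset=0.0,
        )

    p = lmfit.Parameters()
    p.add("kd", value=initial.kd, min=1e-7, max=1e5)
    p.add("delta_h", value=initial.delta_h, min=-1e4, max=1e4)
    p.add(
        "stoichiometry_n",
        value=initial.stoichiometry_n,
        min=0.05,
        max=20.0,
        vary=not fix_stoichiometry,
    )
    p.add("dilution_offset", value=initial.dilution_offset, min=-1e3, max=1e3)

    result = lmfit.minimize(
        _itc_residual, p, args=(h, experiment), method="least_squares", nan_policy="raise"
    )
    if not result.success:
        raise UnidentifiableFitError(f"ITC fit failed: {result.message}")
    rp = result.params
    stderr = {
        name: (rp[name].stderr if rp[name].stderr is not None else np.nan)
        for name in ("kd", "delta_h", "stoichiometry_n", "dilution_offset")
    }
    kd = rp["kd"].value
    rel_err = stderr["kd"] / kd if np.isfinite(stderr["kd"]) else np.inf
    return ITCParams(
        kd=kd,
        delta_h=rp["delta_h"].value,
        stoichiometry_n=rp["stoichiometry_n"].value,
        dilution_offset=rp["dilution_offset"].value,
        stderr=stderr,
        low_confidence=bool(rel_err > 1.0),
    )


@dataclass(frozen=True)
class DoseResponseCurve:
    """Thermophoresis response vs binder concentration at fixed tracer.

    ``binder_concentration`` (µM) must be ascending; ``response`` is the
    normalized thermophoresis signal.
    """

    binder_concentration: np.ndarray
    response: np.ndarray
    tracer_concentration: float

    def __post_init__(self) -> None:
        b = np.asarray(self.binder_concentration, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if b.shape != r.shape or b.ndim != 1:
            raise ValueError("binder_concentration and response must be matching 1-D arrays")
        if np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ValueError("binder concentrations must be non-negative and ascending")
        if self.tracer_concentration <= 0:
            raise ValueError("tracer_concentration must be positive")
        object.__setattr__(self, "binder_concentration", b)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class DoseResponseFit:
    kd: float
    amplitude: float
    baseline: float
    stderr: dict | None = field(default=None, compare=False)


def bound_fraction(binder_uM, tracer_uM: float, kd: float, depletion: bool = True):
    """Fraction of tracer bound at each binder concentration."""
    b = np.asarray(binder_uM, dtype=float)
    if depletion:
        out = np.empty_like(b)
        for i, bi in enumerate(b):
            c = solve_one_to_one(OneToOneSystem(tracer_uM, float(bi), kd)).alpha_as69_bound
            out[i] = c / tracer_uM
        return out
    return b / (b + kd)


def fit_dose_response(curve: DoseResponseCurve, depletion: bool = True) -> DoseResponseFit:
    """Fit ``response = baseline + amplitude * fraction_bound`` for Kd.

    With ``depletion`` on (default) the bound fraction uses the exact 1:1
    equilibrium at each point, correcting the bias that the hyperbolic
    (free ≈ total) isotherm incurs when the tracer is not ≪ Kd.
    """
    b, r = curve.binder_concentration, curve.response
    if len(b) < 6:
        raise ValueError("need at least 6 concentrations spanning the transition")
    noise_floor = np.std(np.diff(r)) / np.sqrt(2.0)
    if np.ptp(r) <= 3.0 * max(noise_floor, 1e-12):
        raise UnidentifiableFitError("no transition in range: amplitude indistinguishable from 0")

    positive = b[b > 0]
    kd0 = float(np.sqrt(positive[0] * positive[-1])) if len(positive) else 1.0

    def residual(p: lmfit.Parameters):
        frac = bound_fraction(b, curve.tracer_concentration, p["kd"].value, depletion)
        return p["baseline"].value + p["amplitude"].value * frac - r

    p = lmfit.Parameters()
    p.add("kd", value=kd0, min=1e-7, max=1e5)
    p.add("amplitude", value=r[-1] - r[0])
    p.add("baseline", value=r[0])
    result = lmfit.minimize(residual, p, method="least_squares", nan_policy="raise")
    if not result.success:
        raise UnidentifiableFitError(f"dose-response fit failed: {result.message}")
    rp = result.params
    stderr = {
        name: (rp[name].stderr if rp[name].stderr is not None else np.nan)
        for name in ("kd", "amplitude", "baseline")
    }
    return DoseResponseFit(rp["kd"].value, rp["amplitude"].value, rp["baseline"].value, stderr)


def oligomer_number_concentration(monomer_equivalents_uM: float, monomers_per_oligomer: float) -> float:
    """Number concentration (µM) of oligomers from their mass concentration.

    3 µM monomer-equivalents at 30 monomers per oligomer is 0.1 µM
    (100 nM) of oligomer particles.
    """
    if monomer_equivalents_uM < 0:
        raise ValueError("monomer_equivalents_uM must be >= 0")
    if monomers_per_oligomer <= 0:
        raise ValueError("monomers_per_oligomer must be positive")
    return monomer_equivalents_uM / monomers_per_oligomer
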