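"""Seeded synthetic data for every fitting stage in the package.

Each generator runs the corresponding forward model (the kinetic
simulators, the ITC mole-balance model, the two-state melt, the
competitive lipid equilibrium, the 1:1 isotherm) and adds additive
Gaussian noise from a single documented generator family
(``numpy.random.default_rng``), so the noiseless output is exactly the
forward model and the noisy output is bit-reproducible under a seed.

``PRESETS`` holds the study conditions the generators emulate, keyed by
the experiment they mimic: strongly seeded elongation (30 µM monomer,
5 µM seeds), weakly seeded secondary nucleation at mildly acidic pH
(70 µM monomer), lipid-induced aggregation (70 µM monomer, 100 µM DMPS)
and the two ITC titration geometries (420 µM into 47 µM at pH 7.4,
320 µM into 32 µM at pH 5, both at 30 °C).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .aggregation_kinetics import (
    LipidNucleationModel,
    SecondaryNucleationModel,
    simulate_lipid_induced,
    simulate_secondary_nucleation,
)
from .equilibrium import CompetitiveLipidSystem, predict_cd_titration
from .thermal_unfolding import MeltingCurve, TwoStateParams, eval_two_state
from .titration_models import (
    DoseResponseCurve,
    ITCExperiment,
    ITCParams,
    bound_fraction,
    simulate_itc,
)
from .trace_analysis import ObservedTrace

__all__ = [
    "NoiseSpec",
    "PRESETS",
    "gen_tht_panel",
    "gen_itc",
    "gen_melting_curve",
    "gen_cd_titration",
    "gen_dose_response",
    "write_with_provenance",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: sigma as a fraction of signal range, explicit seed."""

    sigma: float
    seed: int
    model: str = "additive-gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.model != "additive-gaussian":
            raise ValueError("only additive-gaussian noise is implemented")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: study conditions emulated by the generators (concentrations µM, times h)
PRESETS: dict = {
    # strongly seeded elongation, pH 6.5, quiescent
    "fig4b": dict(
        kind="elongation",
        monomer_total=30.0,
        seed_mass=5.0,
        seed_number=0.025,  # sonicated seeds, ~200 monomers per fibril
        k_plus=1.0,
        kd=0.24,
        t_end=2.0,
        n_points=60,
    ),
    # weakly seeded secondary nucleation, pH 5.0, quiescent
    "fig6b": dict(
        kind="secondary",
        monomer_total=70.0,
        seed_mass=0.07,
        seed_number=1.4e-4,
        k_plus=10.0,
        k2=3.6e-8,
        n2=2.0,
        kd=0.24,
        t_end=40.0,
        n_points=200,
    ),
    # lipid (DMPS SUV)-induced aggregation, pH 6.5, quiescent
    "fig9b": dict(
        kind="lipid",
        alpha_total=70.0,
        dmps_total=100.0,
        kd_alpha_dmps=0.5,
        kd_alpha_as69=0.24,
        l_alpha=30.0,
        kn=1.0e-3,
        nc=1.0,
        k_plus=10.0,
        t_end=10.0,
        n_points=120,
    ),
    # ITC geometries at 30 °C
    "fig1b": dict(
        cell_concentration=47.0,
        syringe_concentration=420.0,
        cell_volume=200.0,
        injection_volumes=(2.0,) * 19,
        temperature=303.15,
        kd=0.24,
        delta_h=-40.0,
    ),
    "fig1c": dict(
        cell_concentration=32.0,
        syringe_concentration=320.0,
        cell_volume=200.0,
        injection_volumes=(2.0,) * 19,
        temperature=303.15,
        kd=0.24,
        delta_h=-40.0,
    ),
}
PRESETS["fig8c"] = PRESETS["fig6b"]


def _simulate_panel_trace(kind: str, params: dict, as69: float):
    t = np.linspace(0.0, params["t_end"], params["n_points"])
    if kind in ("elongation", "secondary"):
        model = SecondaryNucleationModel(
            monomer_total=params["monomer_total"],
            fibril_mass_0=params["seed_mass"],
            fibril_number_0=params["seed_number"],
            k_plus=params["k_plus"],
            k2=params.get("k2", 0.0) if kind == "secondary" else 0.0,
            n2=params.get("n2", 2.0),
            as69_total=as69,
            kd=params["kd"],
        )
        return t, simulate_secondary_nucleation(model, t).fibril_mass
    if kind == "lipid":
        model = LipidNucleationModel(
            system=CompetitiveLipidSystem(
                params["alpha_total"],
                as69,
                params["dmps_total"],
                params["kd_alpha_dmps"],
                params["kd_alpha_as69"],
                params["l_alpha"],
            ),
            kn=params["kn"],
            nc=params["nc"],
            k_plus=params["k_plus"],
        )
        return t, simulate_lipid_induced(model, t).fibril_mass
    raise ValueError(f"unknown panel kind {kind!r}")


def gen_tht_panel(
    kind: str,
    inhibitor_grid,
    noise: NoiseSpec,
    preset: str | None = None,
    params: dict | None = None,
    fluorescence_scale: float = 100.0,
    baseline: float = 50.0,
) -> "list[ObservedTrace]":
    """One noisy ThT trace per inhibitor concentration.

    Fibril mass from the matching simulator is scaled to fluorescence as
    ``baseline + fluorescence_scale * M / monomer_total``; noise sigma is
    a fraction of the uninhibited trace's amplitude so every trace in the
    panel shares one noise level.
    """
    if params is None:
        params = PRESETS[preset or {"elongation": "fig4b", "secondary": "fig6b", "lipid": "fig9b"}[kind]]
    if params.get("kind", kind) != kind:
        raise ValueError(f"preset is for kind {params.get('kind')!r}, not {kind!r}")
    grid = np.asarray(inhibitor_grid, dtype=float)
    m_tot = params.get("monomer_total", params.get("alpha_total"))
    rng = noise.rng()
    traces = []
    amplitude = None
    for a in grid:
        t, mass = _simulate_panel_trace(kind, params, float(a))
        signal = baseline + fluorescence_scale * mass / m_tot
        if amplitude is None:
            amplitude = np.ptp(signal) if np.ptp(signal) > 0 else fluorescence_scale
        noisy = signal + rng.normal(0.0, noise.sigma * amplitude, size=signal.shape)
        traces.append(
            ObservedTrace(t, noisy, {"inhibitor_uM": float(a), "kind": kind, "seed": noise.seed})
        )
    return traces


def gen_itc(params: ITCParams, experiment: ITCExperiment, noise: NoiseSpec) -> np.ndarray:
    """Noisy per-injection heats (µJ); sigma is a fraction of the largest |heat|."""
    heats = simulate_itc(params, experiment)
    scale = np.abs(heats).max()
    return heats + noise.rng().normal(0.0, noise.sigma * scale, size=heats.shape)


def gen_melting_curve(
    params: TwoStateParams,
    t_range: tuple = (283.15, 363.15),
    n_points: int = 161,
    noise: NoiseSpec = NoiseSpec(0.0, 0),
) -> MeltingCurve:
    """Noisy two-state CD melt over ``t_range`` (K); sigma is a fraction of signal range."""
    t = np.linspace(t_range[0], t_range[1], n_points)
    y = eval_two_state(params, t)
    y = y + noise.rng().normal(0.0, noise.sigma * np.ptp(y), size=t.shape)
    return MeltingCurve(t, y)


def gen_cd_titration(
    system: CompetitiveLipidSystem,
    dmps_grid,
    cd_free: float,
    cd_bound: float,
    noise: NoiseSpec,
) -> pd.DataFrame:
    """Noisy CD titration table (columns ``dmps_uM, cd_mdeg``) from the
    competitive binding model; sigma is a fraction of |cd_bound - cd_free|."""
    grid = np.asarray(dmps_grid, dtype=float)
    xb = predict_cd_titration(system, grid)
    cd = cd_free + xb * (cd_bound - cd_free)
    cd = cd + noise.rng().normal(0.0, noise.sigma * abs(cd_bound - cd_free), size=cd.shape)
    return pd.DataFrame({"dmps_uM": grid, "cd_mdeg": cd})


def gen_dose_response(
    kd: float,
    tracer: float,
    noise: NoiseSpec,
    top_uM: float = 2.0,
    n_points: int = 13,
    amplitude: float = 1.0,
    baseline: float = 0.0,
) -> DoseResponseCurve:
    """Noisy two-fold dilution series of the binder against a fixed tracer.

    Concentrations run from ``top_uM`` down by factors of two for
    ``n_points`` points (returned ascending).  The forward model is the
    depletion-exact 1:1 isotherm; sigma is a fraction of |amplitude|.
    """
    conc = top_uM / 2.0 ** np.arange(n_points)[::-1]
    frac = bound_fraction(conc, tracer, kd, depletion=True)
    resp = baseline + amplitude * frac
    resp = resp + noise.rng().normal(0.0, noise.sigma * abs(amplitude), size=resp.shape)
    return DoseResponseCurve(conc, resp, tracer)


def write_with_provenance(df: pd.DataFrame, path: str, provenance: dict) -> None:
    """Write a CSV plus a JSON sidecar recording model, parameters and seed."""
    path = str(path)
    df.to_csv(path, index=False)
    sidecar = path[:-4] + ".json" if path.endswith(".csv") else path + ".json"
    with open(sidecar, "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
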