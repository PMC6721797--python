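# Methods

## Binding equilibria

The 1:1 monomer–inhibitor equilibrium is solved in closed form: the
complex concentration is the smaller root of
`c² − (m_t + b_t + K_d)·c + m_t·b_t = 0`, evaluated as
`2·m_t·b_t / (s + √(s² − 4·m_t·b_t))` with `s = m_t + b_t + K_d` to
avoid catastrophic cancellation in the weak-binding limit. Inputs and
outputs are µM throughout; the admissible root is clamped to
`min(m_t, b_t)` to absorb last-bit rounding at the tight-binding limit.

The three-species competition (inhibitor and lipid vesicles both binding
the monomer) is reduced to one unknown, the free monomer `α_f`. Given
`α_f`, both bound pools follow from the mass-action laws,

    α_b  = D_tot·α_f / (L_α·(K_D,lip + α_f))        (lipid-bound)
    c_b  = A_tot·α_f / (K_D,inh + α_f)              (inhibitor-bound)

and both are strictly increasing in `α_f`, so the monomer mass balance
`α_f + α_b + c_b = α_tot` has exactly one root in `[0, α_tot]`. We
bracket it and use Brent's method at machine tolerance rather than the
closed-form cubic: the cubic's coefficients span many orders of
magnitude over the experimentally relevant range and the root-finding
formulation is uniformly stable, trivially verifiable (the returned
speciation is checked against the raw equations in the tests), and
degrades gracefully to the two-species limits. Residuals are reported on
the `Speciation` object; the default acceptance tolerance is 1e-10 µM
absolute (1e-12 relative to the largest total).

The lipid dissociation constant and stoichiometry are free parameters.
Defaults in the presets — `K_D,α-DMPS = 0.5 µM`, `L_α = 30` lipids per
bound monomer — are representative literature-scale values for
α-synuclein binding to DMPS small unilamellar vesicles; both should be
set to independently measured values when analysing real titrations.

The CD observable `x_b = (CD_mes − CD_free)/(CD_bound − CD_free)` is
returned unclipped. Noisy data legitimately produce values slightly
outside [0, 1]; silently clipping them would bias any downstream fit, so
out-of-range values are passed through with a warning.

## Aggregation kinetics

All three simulators impose monomer sequestration as an *instantaneous
algebraic constraint*: binding of the inhibitor to monomer equilibrates
on seconds, while aggregation proceeds over hours, so at every ODE
evaluation the free monomer is the equilibrium value for the current
unaggregated pool. No explicit binding kinetics are integrated.

**Seeded elongation.** With abundant seeds and negligible nucleation the
initial rate is `2·k₊·m_free·P`, so the sequestration-only prediction
for the relative rate is exactly the free-monomer fraction
`m_free(A_tot)/m_free(0)` — an algebraic identity, tested as such.

**Secondary nucleation.** State `(P, M)` with
`dP/dt = k₂·m^n₂·M` and `dM/dt = 2·k₊·m·P`, `m` the sequestration-
corrected free monomer of the pool `m₀ + M₀ − M`. The factor 2 (two
growing ends per fibril) is a convention that cancels in every relative
rate. Primary nucleation, fragmentation and higher-order assembly
(flocculation) are deliberately omitted: under quiescent conditions in
non-binding plates they are negligible, and the package's question —
how much inhibition can sequestration alone produce — is cleanest
without them. Integration uses LSODA at rtol 1e-8 / atol 1e-12 (1e-9 /
1e-13 for maximum-rate evaluation); trajectories are verified against a
fixed-step RK4 reference at high resolution to <0.1% on the maximum
rate.

The maximum aggregation rate is evaluated from the rate law on a dense
solution (4000 samples of the dense output), never by finite
differencing, with the horizon chosen adaptively: integration stops when
M reaches 99.9% of the total protein, with a generous cap of 60
amplification times `κ⁻¹ = (2·k₊·k₂·m^(n₂+1))^(−1/2)`.

When sweeping reaction orders at a fixed model template,
`k₂` is rescaled by `m₀^(n₂,template − n₂)` so that the uninhibited
reactions complete on comparable timescales; the relative rate is
invariant to this rescaling (both numerator and denominator share `k₂`).

Rate-constant defaults (`k₊ = 10 µM⁻¹h⁻¹`, `k₂ = 3.6e-8 µM⁻¹h⁻¹` at
n₂ = 2 for the 70 µM weak-seed preset, seed mass 0.07 µM at 500 monomers
per seed fibril) were chosen once so that the uninhibited reaction
completes in roughly 20 h, matching the qualitative experimental window;
absolute rates never enter the paper-facing outputs, which are ratios.

**Lipid-induced nucleation.** State `(P, M)` with `dP/dt = kₙ·b^n_c`
and `dM/dt = 2·k₊·f·P`, where `b` (lipid-bound) and `f` (free) come from
the competitive equilibrium of the unaggregated pool. Early-time fibril
mass is quadratic, `M(t) ≈ kₙ·k₊·b₀^n_c·f₀·t²`, verified against the
simulator to 1%; the relative-rate prediction uses the ratio of these
quadratic coefficients, i.e. pure speciation, which equals the ratio of
early rates on any fixed horizon. The default nucleation order is
`n_c = 1` (one-step nucleation from the vesicle-bound state); it is a
model parameter, not a fitted quantity.

## Trace analysis

The initial slope is an ordinary least-squares line over the early
window — by default all points before the signal exceeds baseline + 20%
of amplitude (the data determine the window, not the model). The
maximum rate is the peak of a Savitzky–Golay first derivative (local
quadratic, half-width 5 points by default); non-uniform grids are
linearly resampled first. Both defaults are stated, overridable choices.
Estimates whose maximum rate is below three derivative-noise standard
deviations are flagged rather than rejected. Relative-rate tables
combine replicate scatter (SEM) with per-fit standard errors and
propagate to the ratio at first order.

## Two-state melting

Temperatures are Kelvin internally (°C at the CSV/report interface,
offset 273.15), `R = 8.314 J mol⁻¹ K⁻¹`, ΔH_m carried in kJ/mol, and
ΔCp is fixed at zero — the model has linear folded/unfolded baselines
and a van 't Hoff exponent only. Auto-initialization takes baselines
from the outer 10% of points, T_m from the midpoint crossing, and ΔH_m
from the slope at the crossing via
`dy/dT|Tm ≈ (y_u − y_f)·ΔH_m/(4·R·T_m²)`, clipped to 20–2000 kJ/mol.
Curves whose signal range is within three noise floors of flat are
rejected as unidentifiable; a fitted midpoint outside the measured span
raises a warning. Standard errors come from the curve_fit covariance.

## ITC and MST

The ITC forward model tracks the constant-volume perfusion cell: each
injection of volume dV dilutes cell contents by `1 − dV/V₀` (the
displaced volume leaves the active cell), then adds titrant. The heat of
injection i is `ΔH·V₀·(c_i − c_{i−1}·(1 − dV/V₀))` plus a constant
dilution heat per mole injected; complex concentrations come from the
exact 1:1 equilibrium at the running totals. Real instruments differ in
mixing details; this standard bookkeeping is held fixed and is verified
against an independent mole-balance oracle in the tests. The fitted
stoichiometry n is free by default (it multiplies the cell-site
concentration). Fits in the low c-value regime (cell concentration
below Kd) are returned flagged `low_confidence` when the relative Kd
standard error exceeds 100%.

The MST response is `baseline + amplitude × fraction of tracer bound`
— a linear transform of occupancy, with no temperature-jump
photophysics. With `depletion=True` (default) the bound fraction at
each point is computed from the exact 1:1 equilibrium, so a tracer
comparable to or above Kd (0.1 µM tracer against a 0.03 µM Kd, as in
the oligomer-affinity setting) does not bias the fit; the hyperbolic
`b/(b+K_d)` variant is retained (`depletion=False`) to demonstrate that
bias.

## Synthetic data

Every generator calls the corresponding forward model and adds additive
Gaussian noise from `numpy.random.default_rng(seed)` — one generator
family, one documented noise model, after affine scaling to instrument
units. Noise sigmas are fractions of the relevant signal range (panel
amplitude, |max heat|, melt range, dose-response amplitude). What the
generators deliberately do not emulate: instrument drift, evaporation,
well-to-well gain variation, ThT binding nonlinearity, or fibril-length
dependence of the fluorescence. Parameter-recovery results on these data
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to instrument systematics.

Problem sizes used by the recovery studies (50 seeded replicates; 19
injections; 161-point melts; 13-point dilution series) are the package's
own defaults, chosen to match typical experiment sizes.

## Known limitations

* No global multi-curve fitting of rate constants to kinetic data; the
  kinetic module predicts relative rates from independently measured
  affinities, it does not infer rate constants.
* No saturating (Michaelis-type) elongation, no fibril length
  distributions, no flocculation.
* The non-covalent inhibitor–monomer complex melt is fitted as apparent
  two-state, as is conventional; linked-equilibrium unfolding models are
  out of scope.
* The lipid model treats vesicles as a homogeneous pool of binding
  sites; vesicle size distributions and surface-site geometry are not
  modelled.
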