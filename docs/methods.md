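# Methods

This note records the models implemented in `nanotherm`, the assumptions
behind them, the default parameter choices, and what the test suite does
and does not demonstrate.

## Stratified-sphere Mie optics (`nanotherm.mie`)

**Model.** The particle is a concentric multilayer sphere (magnetite
core, gold shell, polymer coat by default) in a non-absorbing medium.
Per multipole order *n* the layer fields are propagated outward as
effective logarithmic derivatives of the Riccati–Bessel radial
functions (the recursive multilayer formulation in the style of
Toon–Ackerman/Yang). The regular log-derivative D1 is generated by
downward recurrence started 15 orders above the truncation, the
outgoing D3 by the stable upward product recurrence, and the
inner/outer amplitude ratio Q as a bounded iterated ratio — ψ and χ are
never formed inside absorbing layers, which is what makes the recursion
stable for metallic shells. The series is truncated at the Wiscombe
criterion N = ⌈x + 4.05·x^(1/3) + 2⌉. Efficiencies follow the standard
sums Q_ext = (2/x²)Σ(2n+1)Re(aₙ+bₙ), Q_sca = (2/x²)Σ(2n+1)(|aₙ|²+|bₙ|²),
Q_abs = Q_ext − Q_sca, and σ = Q·πR²_outer.

**Conventions.** Time dependence e^(−iωt), so absorbing materials have
Im(n) ≥ 0 (enforced at construction). Wavelengths in nm, cross-sections
in nm² (with an SI accessor for the heat chain).

**Verification.** The test suite checks the engine against an
independent oracle that solves the raw interface boundary conditions per
order as a linear system in 50-digit arithmetic (mpmath half-integer
Bessel functions) — a completely separate code path — to 10⁻⁸ relative
on coefficients and efficiencies, for homogeneous, two-, three-, and
four-layer particles; plus the Rayleigh closed form
q_abs = 4x·Im[(m²−1)/(m²+2)] at x ≤ 0.01, index-matched invisibility,
degenerate-coating reduction, truncation stability, and randomized
energy conservation.

**Default dispersion data.** The packaged gold and magnetite n,k tables
are coarse approximations to the standard literature datasets (sources
in the file headers) and are linearly interpolated in n and k
separately. They are exploratory defaults: users doing quantitative
optics should supply their own `wavelength_nm,n,k` CSV. The polymer coat
defaults to a constant 1.50 + 0i.

**Known limitation.** Real particles of this class have spiky,
"turtle-shell" gold surfaces whose tip plasmons broaden and enhance the
NIR response; the smooth stratified sphere is an idealization and will
generally underestimate NIR absorption. Non-spherical electrodynamics
(DDA/FEM) is out of scope.

## Single-particle heat transport (`nanotherm.heat`)

**Model.** Steady conduction (1/r²)d/dr(k r² dT/dr) = −q_v with uniform
volumetric generation confined to the absorbing (gold) layer,
q_v = P/V_shell, P = σ_abs·I. For spherical symmetry the solution is
exact and piecewise: the region below the source layer is isothermal
(zero enclosed power), inside the shell
dT/dr = −q_v(r³−r_in³)/(3kr²), and everywhere outside the particle
ΔT(r) = P/(4πk_medium·r) independent of internal layering. An optional
finite interface conductance G applies a Kapitza jump q/G at every
interface (perfect contact by default — the interfacial resistance of
these particles is unmeasured). Default medium constants: water,
k = 0.6 W·m⁻¹·K⁻¹, α = 1.43×10⁻⁷ m²·s⁻¹. Default layer conductivities
7 / 317 / 0.2 W·m⁻¹·K⁻¹ (magnetite, gold, polymer).

**Numerical cross-check.** A conservative second-order finite-volume
solver on a face-aligned radial mesh (layer boundaries on cell faces,
harmonic-mean face conductivities, ≥ 20 cells per layer, stretched tail
to ≥ 100 R). The outer Dirichlet value is set to the exact monopole
P/(4πk·r_max) so the measured error is purely discretization; tests
verify < 0.1 % per-node agreement with the closed form, second-order
convergence under refinement, and exact heat-current conservation
(machine precision, by construction of the scheme) through every sphere
enclosing the shell. The numeric path exists as a cross-check; the
analytic solution is the primary path.

**Transient.** The bulk heating curve is modelled by the continuous
point source in an infinite homogeneous medium,
ΔT(r,t) = P/(4πkr)·erfc(r/(2√(αt))), monotone in t and r with the
steady monopole as t → ∞ limit; fitting collapses r/(2√α) into the
single parameter β (s^1/2). The transient is validated against an
explicit time-stepping radial solver at mid-range (r, t) to 0.5 %.

## Ensemble photothermal analysis (`nanotherm.photothermal`)

**Lumped energy balance.** The cuvette is a single thermal compartment:
C_tot·dT/dt = η·I·(1 − 10^(−A₁₀₆₄)) + Q_s − hS·(T − T_amb) with the
laser on, and C_tot·dT/dt = −hS·(T − T_amb) when off. Both segments are
exponentials with τ = C_tot/hS.

**Estimator choices** (made here; the upstream description of this
protocol fixes only the equation forms):

* *hS*: OLS of ln θ vs t on the cooling segment, θ = (T−T₀)/(T_max−T₀),
  discarding the first 5 s after switch-off (sensor lag) and ending the
  default window where θ < 0.05 — the log fit degenerates once the decay
  meets the noise floor. An explicit window overrides both.
* *ΔT_max* is max(T) − T₀ over the first on-block. The balance assumes
  this is the steady-state rise, so traces must be irradiated to plateau
  (≳ 5τ) for η to be unbiased; the packaged scenarios irradiate 30 min
  against τ ≈ 221 s. Note the three printed operating numbers of the
  motivating experiment (3.3 °C·min⁻¹ initial rate, 26 K plateau,
  5-min irradiation) are mutually inconsistent under a single
  exponential; each synthetic scenario therefore reproduces its own
  target quantity rather than all three at once.
* *Q_s* (solvent NIR heat): from the water-only control as
  hS_control·ΔT_max,control with hS_control fitted from the control's
  own cooling — the control obeys the same balance with η = 0.
* *η* outside [0,1] is clamped but flagged (`out_of_range=True`), never
  silently.
* *oSAR*: dT/dt is a centred ±30 s local linear fit at t = 2 min
  (noise-robust vs a two-point difference); window configurable.
* *Heating efficiency at 5 min*: stored heat over delivered optical
  energy, C_tot·ΔT(300 s)/(I·300 s) — a definitional choice made here.
* *Point-source fit*: nonlinear least squares of ΔT∞·erfc(β/√t) from
  five deterministic starts, best residual wins; misfit of a wrong model
  stays visible in `residual_rms`.
* Laser power (W) is stored on the trace; beam area only enters when
  converting to irradiance for the single-particle chain (the ensemble
  balance uses power directly).
* Temperatures are ingested in °C; every derived quantity is a
  difference in K.

## Contrast calibration (`nanotherm.contrast`)

CPMG decays are fitted mono-exponentially S(TE) = S₀e^(−TE/T₂) without
offset (no noise-floor term; an optional constant-offset variant sits
behind a flag). r₂ is the unweighted OLS slope of 1/T₂ (s⁻¹) vs [Fe]
(mM). CT calibration is OLS of HU vs [Au] with the slope referenced to
iohexol (2.7 HU·mM⁻¹). Size summaries use the arithmetic mean and the
n−1 sample standard deviation ("±" read as sd, not sem). DLS
intensity-weighting subtleties are out of scope — DLS samples are
treated as given diameter lists.

## Irradiation planner (`nanotherm.planner`)

Pure deterministic arithmetic: lateral extent nx·field_size ×
ny·field_size, axial depth n_planes·plane_interval (the convention that
makes 38 × 20 µm = 0.76 mm), total time nx·ny·time_per_field, and a
contiguous row-major schedule with half-open field intervals, origin at
the first field's corner, z into tissue. Field side lengths are explicit
inputs rather than derived from a nominal field area, because nominal
"1600 µm²" fields cannot tile an ~11 × 7 mm extent with 8 × 5 tiles; the
packaged example uses 1412.5 × 1434 µm fields, which reproduce the
printed 11.3 × 7.17 × 0.76 mm³ volume exactly. No optics or thermal dose
(CEM43) modelling — only geometry and time.

## Synthetic data (`nanotherm.synthetic`)

Generators are the exact forward models of the estimators, with additive
Gaussian noise everywhere (temperature sensor, high-SNR NMR magnitude,
HU); Rician NMR noise is deliberately deferred. Noisy CPMG signals are
floored at 10⁻¹² to stay positive (magnitude data), which introduces a
small clipping bias only where the decay is far below the noise — the
100-seed recovery tests bound the net bias at < 2 %. All randomness
flows through a `NoiseSpec(sd, seed)` into `numpy.random.default_rng`;
identical inputs are bit-identical.

The packaged operating point (`paper_operating_point`) encodes the
published photothermal state: η = 0.426, I = 1.22 W at 1064 nm,
A₁₀₆₄ = 1.0 (the suspension's absorbance is not published; η is
invariant to this choice when used consistently, which is tested),
C_tot = 4.186 J/K (1 mL water), hS ≈ 0.0189 W/K fixed by the 26 K
plateau split as 24.7 K particle + 1.3 K water contribution, ambient
20.5 °C so the terminal temperature is 46.5 °C. The 1.44 T CPMG design
is unpublished; the low-field generator reuses the 64-echo 7.5–640 ms
design, which comfortably spans the 1.44 T T₂ range (≈ 110–370 ms).

**What passing tests show — and don't.** Round-trip closure proves the
estimators invert their own forward models and are unbiased under the
stated noise; it does not validate the lumped model against a real
cuvette (stirring gradients, sensor placement, laser drift), real CPMG
trains (stimulated echoes, B₁ errors, Rician floors), or real CT
(beam hardening). Those effects are absent from the generators by
design.

## Problem sizes

Default test/reproduction sizes are chosen to keep everything
interactive: traces at 1 Hz (≤ 12 000 samples), 100-seed noise studies,
finite-volume grids of ≤ 1 000 cells, Mie series of ≤ 30 orders. The
full suite runs in well under a minute on one core.
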