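# Methods

This note records the model, the estimator choices, and the numerical
conventions behind `trpkin`, including the points where the design was
genuinely open and what the synthetic-data tests do and do not establish.

## The photocycle model

The package's canonical model is a six-species first-order network for the
photooxidation of the single tryptophan (W48) in apoazurin with a bound
Co(III) acceptor:

```
dG/dt = −k_excit·G + (k_rad+k_ic)·S + (1/τ_T)·T + k_back·C
dS/dt =  k_excit·G − (k_rad+k_ic+k_isc)·S
dT/dt =  k_isc·S − (1/τ_T + k_ET)·T
dC/dt =  k_ET·T − (k_deprot + k_back + k_decay′)·C
dR/dt =  k_deprot·C − k_decay·R
dX/dt =  k_decay′·C + k_decay·R
```

with G the ground state, S the singlet excited state, T the triplet, C the
cation radical, R the neutral radical (the 514 nm observable) and X a
terminal pool of unreactive photoproducts. Assumptions:

* Excitation is a constant first-order rate `k_excit = I₀ σ_A Φ` while the
  light is on and zero otherwise — no photon-depletion feedback, no
  attenuation along the 2 mm excitation path (inner-filter attenuation is
  below 3% at the bench absorbances and is exposed separately as
  `inner_filter_factor`).
* Back-ET returns the cation radical to the ground state; both cation
  decay (`k_decay′`) and neutral-radical decay (`k_decay`) feed the
  terminal sink X, which regenerates nothing and absorbs nothing at
  514 nm. Neither R nor X is re-excited at 280 nm.
* No power-dependent radical decay term: adding one is known to worsen
  fits of this system, so it is excluded by design.

Populations are fractions of the tryptophan pool; the rate matrix has zero
column sums, so Σf = 1 is exact up to integrator error (tested ≤ 1e-6,
typically ≤ 1e-11).

### Canonical constants

| constant | value | origin |
|---|---|---|
| τ_fluo | 3.0 ns | literature lifetime of the apoprotein |
| k_fluo | 3.3e8 s⁻¹ | 1/τ_fluo, quoted at 2 s.f. |
| Φ_isc | 0.3 (default) | maximum radical yield of the Zn protein; 0.2 supported |
| k_isc | 9.9e7 s⁻¹ | Φ_isc·k_fluo |
| k_rad+k_ic | 2.3e8 s⁻¹ | k_fluo − k_isc |
| τ_T | 0.53 s | 450 nm dark decay |
| k_decay | 0.024 s⁻¹ | 514 nm dark decay |
| k_ET, k_deprot, k_back, k_decay′ | 6e6, 3e5, 2e6, 7e5 s⁻¹ | global fit (see identifiability) |

`derive_fixed_constants` rounds k_fluo to the significant figures of the
quoted lifetime (two) before deriving k_isc and k_rad+k_ic, so the
canonical set is internally self-consistent at its printed precision
(9.9e7 rather than the 1.0e8 that exact arithmetic would give); exact mode
is available via `sig_figs=None`.

## Integration and the QSS reduction

The rates span ~10 orders of magnitude against observation windows of
hundreds of seconds. `simulate` offers two paths:

* `bdf` (default): implicit stiff integration with the rate matrix as the
  analytic Jacobian, rtol 1e-8 / atol 1e-10 (configurable);
* `expm`: the exact matrix-exponential solution of the piecewise-constant
  linear system via eigendecomposition (with a per-step `expm` fallback if
  the eigenbasis is ill-conditioned). This is exact and fast, and is what
  the synthetic generators use.

The QSS reduction eliminates S, T, C, which hold ≲1e-8 of the population
under bench conditions when the acceptor is present. Lumping them with G
into a slow pool u gives u →(k_GR) R →(k_decay) X plus a parallel loss
u →(k_GX) X, with

```
k_GR = k_excit·Φ_isc·p_ET·p_deprot,  k_GX = k_excit·Φ_isc·p_ET·p_x,
p_ET = k_ET/(k_ET + 1/τ_T),          p_i  = k_i / (k_deprot+k_back+k_decay′)
```

solved in closed form segment by segment (two exponentials; the d→a
degenerate case switches to a series form below |(d−a)s| < 1e-8). The
reduction warns when `k_excit` is not small against the fast-species decay
rates (threshold 0.01). Full integration and closed form agree on f_R to
~1e-9 with acceptor present and to ≤1e-4 in the acceptor-free regime the
validity test covers; the reduced model is the default fitting engine,
with the full ODE retained as a verification engine (objectives agree to
0.1% on bench-scale data).

`steady_state_triplet` is the two-state balance x/(1+x), x = k_excit·Φ_isc·τ_T,
for the acceptor-free 450 nm plateau.

## Trace estimators

* **Drift**: a straight line fitted by OLS on a light-off window
  (≥10 points) and subtracted from the whole trace. With the generator's
  230 s pre-illumination window the residual slope error is negligible
  against the signal; the round-trip identity is tested to ≤1e-5 AU RMS
  for any slope within the instrument bound.
* **Monoexponential fits** default to zero offset (baselines are
  pre-subtracted); an offset term is available by flag. Noiseless recovery
  is exact to 1e-6 relative over τ ∈ [0.1, 100] s; a 100-replicate
  calibration test bounds the bias at 1% and checks the reported standard
  errors against the empirical spread within a factor of 2.
* **Initial rates**: `initial_rate` fits an OLS quadratic in time over the
  window and reports the linear coefficient — the rate at the window
  start. With k_decay = 0.024 s⁻¹ the radical already turns over during
  any usable window, and a plain straight-line slope over the 30 s default
  window underestimates the true initial rate by ~30%; the quadratic
  estimator's bias is −4.6% at 30 s and its single-run RMSE on the yield
  (~5%) beats every straight-line window length (analytic bias/variance
  computation, verified against the noiseless generator). The plain slope
  remains available as `model="linear"`.
* **Quantum-yield regression** runs through the origin by default (zero
  excitation must give zero radical); free-intercept mode is a diagnostic.
  Excited-state formation rates use the thin-sample (linear, ln10·A_W48)
  absorbed-light convention by default, which is exactly the convention
  under which `k_excit = I₀σΦ` is defined — at the bench absorbance
  (A₂₈₀ ≈ 0.11) the saturating 1−10^−A form would shift the yield by
  ~14% and is provided as an option. The emission module, where the
  measured quantity is genuinely "light absorbed by the solution",
  defaults to 1−10^−A (switchable). An `illuminated_fraction` scalar
  (default 1: full beam/probe overlap) rescales molecule counts.

## Global fit and identifiability

Free parameters (k_ET, k_deprot, k_back, k_decay′) are optimized as log10
values with bounds [1e0, 1e10] s⁻¹ (positivity over the network's dynamic
range); all traces are weighted equally; uncertainties come from the
Jacobian-based covariance at the optimum, propagated from log space.

The observable depends on the free constants only through p_ET (saturated
at 1 for any k_ET ≫ 1/τ_T) and the branching probabilities p_deprot, p_x.
Consequently k_ET and the common scale of the cation-branch rates are
exactly flat directions: any one cation rate can be rescaled and
compensated by the other two. `profile_flatness` measures this directly —
the parameter is clamped on a log grid while the others are re-optimized;
a relative objective change below 1e-2 flags the parameter as flat. Under
bench conditions all four individual rates are flagged; point values along
flat directions reflect the initialization and are labelled as such in
every report.

The initialization recipe is fixed a priori: k_ET, k_back and k_decay′
start at a common 1e6 s⁻¹ scale (forward and back ET cross the same
donor–acceptor pair, so a shared magnitude is the natural prior; the two
non-productive cation channels split 50/50), and k_deprot is set so the
one-pass yield matches the measured initial-rate yield divided by Φ_isc.

What is identifiable is reported with honest uncertainty:
`p_deprot_estimate` returns the branching probability with a delta-method
standard error built from a finite-difference model Jacobian
pseudo-inverted within the identifiable subspace only, so the formally
infinite flat-direction variance cannot leak in. A 50-replicate drift-free
study shows |bias| < 5% and ±1 SE coverage in the 50–95% range; the
drift-corrected pipeline adds a correlated per-trace tilt that the
white-noise SE deliberately does not model, which inflates the spread of
p̂_deprot by ~2.5× — a known limitation, not a defect of the fitter.

`sensitivity_phi_isc` re-derives k_isc/k_rad+k_ic per Φ_isc and refits;
between Φ_isc 0.2 and 0.3 the recovered one-pass yield is invariant and
the shift is absorbed mainly by k_back, as expected from the branching
structure.

A corrupted fixed k_decay (×10) strictly worsens the optimum — k_decay is
the only fixed constant the free parameters cannot compensate; corruption
of k_isc, k_rad+k_ic or 1/τ_T is largely absorbed by the flat directions,
so no monotone-misfit claim is made for those.

## Emission yields

Trapezoidal band integrals with interpolated endpoints, so adjacent bands
tile the full-range integral exactly; band edges are closed intervals
(the shared 400 nm point belongs to both bands; on a ≥1 nm grid the
double-counting is nil because integration, not summation, is used).
Yields follow Φ_band = Φ_ref·[I_band/(α_s f_s)]/[I_ref/α_r] with
α = 1−10^−A. No refractive-index correction (same solvent) and no
instrument spectral-response correction.

## Structural fluctuation

Superposition uses the SVD (Kabsch) solution with a proper-rotation
constraint; collinear or coincident point sets are rejected. An
independent quaternion-eigenvalue oracle in the tests agrees to 1e-10
RMSD. RMSF aligns every frame to the first frame (unweighted, Cα only)
and by default measures fluctuations about the post-superposition *mean*
position — the standard convention, recorded in the profile's policy
field; frame-1-referenced deviations are available and are never smaller.
Fitting 6 rigid-body degrees of freedom absorbs ~6/(3N) of the variance,
so quantitative RMSF convergence (e.g. the s√3 isotropic-jitter limit)
requires N ≫ 2. Residue numbering follows the input file verbatim.

## Synthetic data: what it does and does not emulate

The generators reproduce the bench acquisition: 0.1 s sampling, Gaussian
white noise of 2e-4 AU (an instrument-plausible floor; only the drift
bound is documented for the real instrument), a linear drift at the stated
maximum of 0.001 AU per 300 s, a 230 s pre-illumination baseline, 330 s of
light and 300 s of darkness at six incident powers (0.80–0.10 mW on a
0.64 cm² beam — the 8×8 mm "squircle" spot is treated as a full square, a
config field rather than a constant), 75 µM protein probed over 1 cm with
ε₅₁₄ = 2200 M⁻¹cm⁻¹. The triplet trace uses a free extinction scale at
450 nm (5000 M⁻¹cm⁻¹) because only the plateau shape and decay constant
matter. Emission spectra are built from Gaussian components whose band
areas are solved exactly (via the band-overlap matrix) to make the
declared yields the true ones under the declared convention; trajectories
jitter about a rigid helical scaffold with per-residue amplitudes and
optional global rigid motion.

Not emulated: 1/f or correlated instrument noise, photoselection and
polarization, LED lineshape (12 nm fwhm band is collapsed to its centre),
re-excitation of photoproducts, the dual 280+405 nm photoionization
channel, and any spatial beam/probe overlap profile beyond a scalar
fraction. Passing tests therefore demonstrate estimator correctness and
calibration under white noise and bounded linear drift, not robustness to
every instrument pathology.

## Problem sizes

Default test and acceptance runs use the full 0.1 s grids (≈8,600 points
per trace, six traces) for single fits, a 0.5 s grid for the 50-replicate
calibration study, and 10⁴ frames × 300 atoms for the RMSF convergence
check; these sizes keep every study well-resolved while the whole suite
runs in well under a minute.

## Known limitations

* Individual cation-branch rate constants and k_ET are not identifiable
  from 514 nm kinetics alone; the package reports them as flat directions
  and treats p_deprot (and combinations such as the one-pass yield) as the
  estimands.
* The drift-correction uncertainty is not propagated into downstream
  standard errors.
* The initial-rate quadratic estimator still carries a small negative
  bias (≈5% at the default window) that is inherent to windowed rate
  estimation on a turning-over signal.
* Multi-exponential decays, spectral decomposition into species basis
  spectra, and Marcus free-energy analysis are out of scope.
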