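# Methods

This note documents the models implemented in `fccs_kin`, their
assumptions, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Measurement model

### Detection geometry

Each confocal channel has a 3D-Gaussian detection profile
W(r) = exp(−2(x²+y²)/w_xy² − 2z²/w_z²) with lateral waist w_xy and axial
radius w_z = s·w_xy. The effective volume V_eff = π^{3/2} w_xy² w_z
converts concentration to mean occupancy N = c·N_A·V_eff; the fitted
autocorrelation amplitude of one freely diffusing species obeys
G(0) = 1/N.

The instrument parameters of the original setup are not published, so the
package ships conventional defaults, all overridable: w_xy = 0.25 µm,
s = 5, molecular brightness 30 kcps per dye at beam center, zero
background and zero spectral cross-talk. The nanopore carries 10 red dyes
and the ligand one green dye; complex brightness is additive (no
quenching modeled). Diffusion coefficients follow Stokes–Einstein scale
estimates: 1.1×10⁻¹¹ m²/s for the 46-nm origami pore (and the complex,
which diffuses like the pore), 1.0×10⁻¹⁰ m²/s for the 20-nt ssDNA ligand.

### Optical overlap

Imperfect overlap of the two detection volumes caps the cross-correlation
amplitude. It is summarised by one multiplicative efficiency f_ov
(default 0.60, the value of a double-labeled calibration control:
`calibrate_overlap`). Internally the simulator realises f_ov *physically*
as a lateral displacement d of the red volume with f_ov = exp(−d²/w_xy²):
this reduces the simulated cross amplitude by exactly f_ov, leaves both
autocorrelations untouched, and gives the cross-correlation the known
displaced-volume lag dependence

    G_x(τ) ∝ shape(τ) · exp(−d²/(w_xy²(1+τ/τ_D))),

which the cross fit uses (`g_cross_displaced`, normalised so G0 remains
the τ = 0 amplitude). Measured CCP values are never divided by f_ov; the
ceiling is absorbed by the plateau parameter A of the kinetic fits,
mirroring the original analysis.

### Photon-trace simulation

Particles of the three species (free pore, free ligand, complex) perform
Brownian steps (per-axis SD √(2DΔt)) in a periodic rectangular box of
6w_xy × 6w_xy × 6w_z: the profile at the ±3w boundary is e⁻¹⁸ of its
peak, so effectively all detected signal
originates far from the boundary while no dark volume is simulated. The
time step is Δt = min(bin width, w_xy²/(20·D_max)) — at most one step per
bin, refined whenever a step would cross a substantial fraction of the
beam waist; sub-bin stepping beyond that resolution adds nothing
physical. Expected per-bin counts are path integrals of q·W(r) along each
trajectory; realised counts are Poisson draws (shot noise). Trajectories
and profile evaluations run in float32 (rounding ~10⁻¹³ m against
3×10⁻⁸ m steps — invisible under shot noise); accumulators are float64.
Per-species particle numbers are round(c·N_A·V_box); in a ~17 fL box this
rounding shifts realized concentrations by up to several percent, so
validation tests compare against the realized integer counts recorded in
the trace metadata. Identical configuration and seed give bit-identical
traces (independent deterministic sub-stream per species plus one
shot-noise stream).

Binding does not toggle during a trace: traces last seconds to minutes
while binding relaxes over minutes to hours, so species populations are
frozen at the incubation-time values (free-ligand reservoir
approximation) and pseudo-first-order state switching is provided
separately (`simulate_state_switching`) for constructing time courses.
Photophysics beyond Poisson emission (triplet blinking, bleaching,
saturation) is out of scope.

### Correlation

`G(τ) = ⟨δF_A(t)δF_B(t+τ)⟩/(⟨F_A⟩⟨F_B⟩)` with symmetric normalisation:
all averages run over the admissible lagged windows, which immunises the
estimator against slow drift. The multi-tau scheme uses m = 16 lags per
level, halving time resolution per level by pairwise averaging, with the
level count chosen so the longest lag is roughly a tenth of the trace
(longer lags are noise-dominated). Level-0 values agree with the direct
O(N·L) estimator to floating-point precision — the direct estimator is
the test oracle, not a decoration. The shot-noise-dominated lag-0 point
is never reported. Per-lag errors come from correlating 8 (configurable)
contiguous trace segments and taking the standard error of the mean.

### Amplitude fits and CCP

Correlation curves are fitted with the single-component 3D-Gaussian model
G(τ) = G0 (1+τ/τ_D)⁻¹ (1+τ/(s²τ_D))^{−1/2}, s fixed by calibration, by
weighted least squares (1/G_err² when per-lag errors exist). Cross curves
fix τ_D to the fitted red-channel diffusion time (the complex diffuses
like the pore) and use the displaced-volume factor; the amplitude then
solves in closed form. Negative fitted cross amplitudes are retained and
flagged, never clipped, so titrations stay unbiased near zero binding.
CCP = 100·G_x(0)/G_L(0) with first-order error propagation.

Because the ligand channel mixes a fast free-ligand and a slow complex
population, the single-component τ = 0 extrapolation carries a systematic
mixture bias; two-component fitting is deliberately out of scope. With
20 µs bins the residual bias is +7–9% of CCP across bound fractions
(validated end to end against the analytic amplitude relations), which is
why the end-to-end consistency checks use a 15% band.

## Kinetic models

* Exact generating model: dC/dt = k_on(P0−C)(L0−C) − k_off·C, integrated
  with LSODA at rtol 10⁻¹⁰ (`bound_fraction_ode`); equilibrium from the
  cancellation-free quadratic root 2P0L0/(b+√(b²−4P0L0)), stable down to
  K_d → 0. Tests check it against the closed-form Riccati solution.
* Two-ligand competition (`displacement_ode`): labeled and unlabeled
  ligand with identical kinetics compete for the pore; the labeled
  complex decays almost single-exponentially at rate k_off once the
  competitor is in large excess (~3% residual rebinding at the published
  30 nM/1000 nM protocol — inside the 10% recovery band).
* Fits (statsmodels-style Model → Results with params, standard errors,
  covariance, `summary()`): exponential equilibration, weighted rate-law
  line (statsmodels WLS; the intercept is reported but flagged
  `unreliable_intercept` and never used for k_off — extrapolation to
  [L] = 0 is ill-conditioned), hyperbolic isotherm with Hill exponent
  fixed at 1, depletion-corrected isotherm CCP = A·C_eq(P0,[L],K_d)/P0
  (the tight-binding stand-in required when K_d ≲ P0, tagged
  `depletion-corrected` in output metadata), and the displacement
  exponential with free offset.
* Closure K_d = k_off/k_on (`complete_affinity`): the third constant of
  any measured pair, uncertainty by quadrature of relative errors,
  provenance marked `derived-via-closure` in every record.

### Numerical choices

Bounded trust-region least squares cannot step usefully when parameters
span ten decades (A ≈ 60 vs K_d ≈ 10⁻⁹), so every fit rescales its
parameters to O(1) around the start internally. The depletion isotherm
additionally seeds from a profiled-amplitude scan over log₁₀K_d — its SSR
surface is nearly flat in K_d below P0 and defeats cold starts.
Initialisation: A from the data maximum, k_eq and k_off from a half-life
heuristic, K_d from the half-maximum concentration. Rates and K_d are
bounded positive; amplitudes and the displacement offset are free.
Degenerate inputs (all-zero or constant data) return flagged,
non-converged results rather than raising mid-pipeline.

## Synthetic experiments

`generate_dataset` renders each built-in design (the six published
receptor–ligand conditions with their printed concentration series,
1.3 nM pore, 180 min equilibration, and the two displacement protocols)
into time courses, a titration and (antibody) a decay.

* CCP-level mode evaluates the pseudo-first-order reservoir forward model
  CCP(t) = A·f_eq·(1−e^{−k_eq t}) — the same model family the analysis
  fits — plus additive Gaussian noise of SD 2 CCP points (the default
  noise model; tunable, photon-level available). The full
  depletion-aware ODE is available via `model="ode"` and is what the
  bias demonstrations use. Streptavidin titrations always come from the
  depletion equilibrium: at K_d = 4 pM and P0 = 1.3 nM the reservoir
  isotherm is flat and K_d unidentifiable, which is precisely why the
  tight-binding fit exists.
* Photon-level mode routes each sampled point through simulator →
  correlator → amplitude fits → CCP (50 s traces, 20 µs bins by
  default).

`run_titration_analysis` chains equilibration fits → rate law → isotherm
→ closure. Titration points are first divided by the fitted
1−e^{−k_eq·t_eq} of the matching time course: at 180 min the slowest
published condition is only ~92% equilibrated and the uncorrected
isotherm would overestimate K_d by ~20%. Antibody conditions
(equilibration faster than the measurement dead time) take the
isotherm + displacement route and derive k_on. `reproduce_affinity_table` runs
all six conditions noiselessly and with default noise; noiseless
recoveries sit within ~3% of the printed constants — the residual is the
rounding of the printed triples themselves, which are not exactly
closure-consistent.

## What the tests show — and what they don't

The original raw instrument traces are not available, so measurement-level
behaviour is validated *by construction*: seeded simulations with known
ground truth (amplitude law G0 = 1/N, diffusion-time recovery, end-to-end
CCP vs the analytic amplitude relations, estimator cross-checks against
brute force), and inference-level behaviour by inverting the package's
own forward models at the published experimental designs. Passing these
tests demonstrates internal consistency and correct implementation of the
analysis chain at realistic signal levels; it does not certify vendor
hardware effects absent from the model (afterpulsing, dead time, triplet
kinetics, detector cross-talk) or the accuracy of the printed constants
themselves. Problem sizes in the default suite (30–100 s traces, 5 seeds
per condition, 100-seed noise studies) were chosen as the smallest runs
whose Monte-Carlo scatter sits comfortably inside the asserted bands.

## Known limitations

* Single-component correlation fits only; the documented mixture bias is
  the price of matching the published amplitude-only analysis.
* The reservoir generator and the exponential/rate-law/isotherm analysis share a model family
  (an "inverse crime" when used for recovery tests); the depletion-aware
  ODE mode exists to break that symmetry where it matters.
* No spatial model of the pore lumen: confinement enters only through the
  kinetic constants, as in the study design.
* No vendor raw formats; traces are CSV with JSON sidecars.
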