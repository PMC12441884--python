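# Methods

## Scope and units

`mrcyt` models isotropic two-compartment tissue water in time-dependent
diffusion MRI and the downstream lesion-classification statistics.  Units are
fixed package-wide: time in ms, gradient amplitude in mT/m, b-values in
ms/μm² (1 ms/μm² = 1000 s/mm²), diffusivities in μm²/ms, exchange rates in
1/s at the API (converted to 1/ms internally).  γ = 2.67513×10⁻⁴
rad·μm⁻¹·ms⁻¹ per mT/m (the proton value 267.513×10⁶ rad s⁻¹ T⁻¹).

## Waveforms and protocol

Waveforms are ideal rectangles (PGSE) and midpoint-sampled cosines (OGSE)
without slew ramps; because all signal models integrate the *sampled*
waveform numerically, trapezoidal ramps could be added later without API
changes.  The default sampling step is 5 μs, giving <0.1% b-value
discretization error at 50 Hz.  Effective diffusion times are Δ − δ/3 for
PGSE and 1/(4f) for cosine OGSE (5 ms at 50 Hz, 10 ms at 25 Hz).

The default three-sequence protocol is PGSE (δ=12, Δ=74 ms, t_d = 70 ms) at
b ∈ {0, 0.25, 0.5, 1.0, 1.5}; OGSE 25 Hz (one period per lobe) at
b ∈ {0, 0.3, 0.6, 1.0}; OGSE 50 Hz (two periods per lobe) at
b ∈ {0, 0.25, 0.5} ms/μm².  Each sequence carries its own b = 0 anchor.
The gradient cap defaults to 80·√3 ≈ 138.6 mT/m — the effective amplitude
when an 80 mT/m-per-axis system drives all three axes together, which is the
only way a 50 Hz cosine waveform of this duration reaches b = 0.5 ms/μm²;
this is also why the 50 Hz arm stops at b ≤ 0.5 while requesting b = 1.0 at
50 Hz raises a hardware-limit error.

## Intracellular signal (GPA)

For water restricted in a sphere of radius R = d/2 the Gaussian phase
approximation gives

ln S = −γ² Σₙ Bₙ Jₙ,  Jₙ = ∫₀^TE g(t) ∫₀^t g(t′) e^(−D_in(αₙ/R)²(t−t′)) dt′ dt,

where αₙ are the ascending roots of α·j₁′(α)=0 and Bₙ = 2(R/αₙ)²/(αₙ²−2),
so that Σₙ Bₙ = R²/5 is the one-axis equilibrium position variance.  The
prefactor is pinned by the narrow-pulse long-time limit S → exp(−q²R²/5) and
is verified in the test suite against (a) the standard two-rectangular-lobe
closed form, (b) an independent O(T²) double-sum quadrature, and (c) a
Monte-Carlo random walk.  The double integral is evaluated with the exact
exponential-kernel recursion for piecewise-constant samples, so the result
is exact for the sampled waveform (no additional time-discretization error).
20 eigenmodes are used by default with an automatic tail check that doubles
the mode count (up to 80) if the last mode contributes more than 10⁻⁶ of the
sum.

## Composite models and the exchange engine

IMPULSED: S = v_in·S_sphere + (1−v_in)·exp(−b·D_ex), free parameters
(d, v_in, D_in, D_ex), no exchange.

JOINT / EXCHANGE: the two pools are coupled by transcytolemmal water
exchange.  The magnetization pair M = (M_in, M_ex) evolves as dM/dt = A(t)M
with

A(t) = [[−R_in(t) − k_in, k_out], [k_in, −R_ex(t) − k_out]],

R_in(t) the instantaneous GPA dephasing rate of the waveform (the time
derivative of −ln S_in up to t), R_ex(t) = D_ex·q(t)², and detailed balance
k_out = k_in·v_in/(1−v_in) (equilibrium mass balance; only k_in is
reported).  A(t) is piecewise constant at waveform resolution and each step
uses the closed-form 2×2 matrix exponential, so the propagation is exact for
the discretized system; a step-by-step `scipy.linalg.expm` propagation is
kept as an independent oracle in the tests.  At k_in = 0 the engine
reduces to IMPULSED to machine precision because both paths share one
discretization of the waveform (worst deviation ~10⁻¹² over random
parameter sweeps).  D_in is fixed at 1.56 μm²/ms in both exchange variants
to stabilize the four-parameter fit.

JOINT and EXCHANGE are exposed as two named configurations over this single
forward engine.  The published descriptions that distinguish them live in
supplementary material and upstream references that specify the same free
parameter set (v_in, d, D_ex, k_in); with no printed mathematical
difference, the two names here produce identical fits by construction, and
the duplication is retained only so that report tables carry all three
model families.

## Fitting

Per voxel, signals are first normalized by the b = 0 acquisition of their
own sequence (removing T2/TE differences between sequences; voxels with a
non-positive anchor, any normalized signal > 1.2 or ≤ 0, or non-finite
values are excluded and counted).  ADC per sequence is the through-origin
regression of ln S on −b, clipped at zero; ΔADC defaults to the relative
form (ADC_50Hz − ADC_PGSE)/ADC_PGSE, with the absolute difference available
as a mode.  An optional flag drops b < 0.2 ms/μm² from ADC fits to blunt
perfusion (IVIM) contamination; it is off by default since no specific
procedure is prescribed.

Model fits use trust-region reflective least squares with numerical
Jacobians (ftol = xtol = 10⁻¹⁰) inside bounds d ∈ [5, 30] μm, v_in ∈ [0, 1]
(capped at 0.999 for the exchange models to keep the detailed-balance
closure finite), D_in ∈ [0.5, 3.0], D_ex ∈ [0.3, 3.5] μm²/ms,
k_in ∈ [0, 50] s⁻¹ — brackets chosen to enclose reported breast-tumor values
with margin.  Initialization is a deterministic 16-point Latin hypercube;
the best 4 points by initial residual are polished and the lowest-RSS
solution returned.  Optimizer failure never raises: a non-converged result
carries flags instead.  Fits are bit-reproducible given (signal, protocol,
config seed).  During optimization the protocol is resampled to a 0.1 ms
waveform grid — the forward models are exact for the sampled waveform, so
this only trades waveform-shape resolution (≈0.1% in b at 50 Hz) for a
~20× speedup.  ROI summaries are arithmetic means of voxelwise estimates
over converged voxels (the voxelwise-then-average convention), with a
warning flag when more than half the voxels fail to converge.

## Synthetic cohorts

The generator emulates the study conditions the statistics assume: 90
lesions composed 26/38/18/8 (Luminal A / Luminal B / TNBC / HER2-enriched).
Per subtype, d, v_in, k_in and D_ex follow log-normal distributions whose
median/IQR equal the published exchange-model ROI statistics (e.g. d medians
13.67–15.07 μm with HER2-enriched largest; k_in 6.7–8.1 s⁻¹), and D_in
follows the impermeable-model row (~2.05–2.15 μm²/ms); the log-normal shape
parameter is σ = asinh(IQR/2m)/z₀.₇₅, the closed form matching a given
median and IQR for a positive, right-skewed variable.  IHC labels are drawn
with subtype-conditional probabilities taken from the cohort composition
(TNBC forced triple-negative, Luminals forced ER+, HER2-enriched forced
HER2+).  Lesions get a lesion-level parameter draw with 5% multiplicative
voxel jitter (so ROI averaging is non-trivial); ground-truth signals come
from the exchange forward model (k_in > 0), which is what makes the
impermeable model's v_in underestimation observable; Rician noise
S′ = √((S+ε₁)² + ε₂²) with σ = 1/SNR is added at a default SNR of 50 at
b = 0, a typical clinical breast-dMRI figure.

Because the cohort's true D_in (~2.1 μm²/ms) differs from the 1.56 fixed in
the exchange fits, the end-to-end pipeline is deliberately mis-specified in
the way a real study is; the parameter-recovery experiments instead generate
at D_in = 1.56 so that "recovery" is well defined.  What the synthetic
cohort does **not** emulate: perfusion/IVIM signal, relaxation differences
between compartments, cell-size dispersion within a voxel, non-spherical
geometry, spatial correlation of parameters, and EPI/k-space artifacts.
Passing tests therefore validate the estimation machinery under the model's
own assumptions, not clinical accuracy on real tissue.

The Monte-Carlo oracle walks ≥10⁴ spins with Gaussian steps (σ = √(2D dt)
per axis) and specular reflection at the sphere boundary, accumulating phase
γ·g(t)·x(t)·dt; the step length √(6D dt) is required to stay below d/10.
With 2×10⁵ walkers its agreement with the GPA is ~0.1–1% of signal across
d ∈ {10, 15, 20} μm and all three sequences — GPA error grows with
attenuation, and the 2%-of-signal validation band reflects that.

## Statistics

Group comparisons use the two-sided Mann–Whitney U test (exact enumeration
for tie-free samples with both n ≤ 8, tie-corrected normal approximation
otherwise) and the tie-corrected Kruskal–Wallis H with χ² p-values.
Classifiers are unregularized maximum-likelihood logistic regressions on
standardized features; the reported AUC is the apparent (in-sample) rank
statistic of the fitted probabilities, which for a single feature equals the
normalized Mann–Whitney statistic (verified exactly by pairwise enumeration
in the tests — an optimistic estimate by construction, matching common
clinical-study practice).  Confidence intervals are stratified percentile
bootstraps (2000 resamples by default, seeded); resample refits use an
internal IRLS Newton solver cross-checked against statsmodels.  P-values are
Wald for single-feature models and likelihood-ratio versus the
intercept-only model for combined models; both are retained on the report
object.  No multiple-testing correction is applied by default.  Perfect
separation is flagged and reported as AUC 1.0 with unreliable coefficients.
Feature sets mirror the study design: all four ADC metrics combined, and per
model all fitted parameters plus cellularity.

## Numerical choices and degenerate inputs

- Eigenmode roots are bracketed by grid scan and polished with Brent's
  method to 10⁻¹⁴; roots are cached process-wide (they are radius-free).
- κ·dt < 10⁻¹⁰ and q·dt < 10⁻⁸ switch to series forms in the kernels.
- v_in = 1 with k_in > 0 raises a degenerate-balance error (no extracellular
  pool); v_in = 0 collapses to pure hindered signal.
- Zero-amplitude waveforms give b = 0 and S = 1 exactly and cannot be
  rescaled to b > 0.
- All-tied samples return p = 1 with an explicit flag rather than an error.
- ΔADC in relative mode returns NaN when ADC_PGSE = 0.

## Problem sizes in the validation suite

The acceptance tests use 2×10⁵ Monte-Carlo walkers per physics comparison,
200 recovery voxels per subtype at SNR 50, 100-point reduction sweeps, 200
bootstrap-coverage replicates (2000 resamples each), and 20 cohort seeds for
the classification contrast.  That contrast isolates the manipulated
variable: per-subtype cell diameters with one pooled prior for the other
parameters and 4-voxel ROIs — under the full per-subtype priors the
generated ADC_PGSE (driven by the tight HER2-enriched D_ex distribution) is
nearly as discriminative as the diameter itself, a property of the
generative model rather than of the estimators.  The deterministic-pipeline
check runs the full-prior cohort at 2 voxels/lesion with 200 bootstrap
resamples.  `scripts/acceptance.py` runs the same experiments at 5×10⁴
walkers, 50 voxels per subtype and 5 cohort seeds per cohort variant.

## Known limitations

- GPA accuracy degrades at strong attenuation and large cells (worst ~1% of
  signal at b = 1, d = 20 μm against Monte Carlo here); fitted-parameter
  biases inherit this.
- k_in is the least identifiable parameter at b ≤ 1.5 ms/μm²; its bounds
  and the multi-start density matter more than for the geometric parameters.
- The apparent AUC is optimistic; a cross-validated variant is not part of
  the default reports.
- JOINT and EXCHANGE are numerically identical here (see above); columns are
  duplicated, not independently informative.
- The high-frequency approach of the apparent intracellular diffusivity to
  D_in is slow (~1/√f): ~10% deviation remains at 500 Hz for d = 10 μm,
  crossing 5% only near 2–3 kHz.
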