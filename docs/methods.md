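# Methods

## Signal models

All computation assumes the spoiled gradient-echo (FLASH) steady state
with perfect spoiling of transverse magnetization at the end of each TR
(the Ernst regime).  Three algebraically related forms are implemented:

1. **Ernst equation** — S = A sin(α)(1−E)/(1−cos(α)E), E = exp(−R1·TR).
2. **Half-angle tangent form** — with τ = 2 tan(α/2),
   S = A τ (1−E) / ((1−E) + (τ/2)²(1+E)).  Exactly equivalent; rational
   in τ.
3. **[1/1] Padé approximant** of form 2 around R1·TR = 0:
   S ≈ A τ R1·TR / (τ²/2 + R1·TR).  Its relative error is controlled by
   R1·TR alone (asymptotically quadratic: halving R1·TR cuts the
   residual by a factor approaching 4), *not* by the flip angle — which
   is what makes estimators derived from it accurate at large angles.

Units are seconds and radians throughout the library; degrees,
milliseconds and percent are converted at CLI/config boundaries.  The
transmit-field scale ft (actual/nominal flip angle) is a dimensionless
fraction.  1−E is evaluated as −expm1(−R1·TR), which is accurate down
to arbitrarily small R1·TR; the naive difference loses precision
exactly in the short-TR regime the method targets.

## Estimators

* **`estimate_pade`** — exact closed-form inversion of the Padé model
  for two volumes; flip angles arbitrary, TRs may differ.
* **`estimate_small_angle`** — the conventional closed form: identical
  algebra with α substituted for τ.  Biased when actual angles are
  large; kept as the comparison baseline.
* **`estimate_exact_equal_tr`** — exact two-point Ernst inversion via
  E1 = (S1/sin α1 − S2/sin α2)/(S1/tan α1 − S2/tan α2); only defined
  for TR1 = TR2.  Validated by round-trip and by agreement with the
  nonlinear fit (no printed reference expression exists to compare
  against).
* **`despot1_fit`** — the Padé model rearranges to the line
  y = A − x/(2R1) with x = Sτ/TR, y = S/τ; unweighted ordinary least
  squares over N ≥ 2 volumes (the canonical DESPOT1 weighting choice).
  With N = 2 it reduces algebraically to `estimate_pade`.
* **`nonlinear_fit`** — least squares on the half-angle-tangent Ernst
  form in (log R1, log A); the log parameterization enforces positivity
  without constrained optimization.  Slow, per-voxel; used as the
  accuracy oracle.

Error handling separates two regimes deliberately.  Per-voxel failures
— zero denominators, E1 outside (0,1), non-positive or non-finite
parameters — are routine in noisy background voxels and yield
`valid=False` with NaN outputs and a cause code tallied in the summary
log, never an exception.  Protocol-level degeneracies (equal effective
flip angles, rank-deficient designs, exact estimator with unequal TRs)
raise immediately: they indicate misconfiguration, not noise.  No
clipping of R1 or A to physiological ranges is applied anywhere in the
estimators; range masking belongs to analysis layers.

### A subtlety of the small-angle limit

One might expect the small-angle and Padé estimates to converge as the
flip angles are scaled to zero at fixed R1·TR, since τ/α → 1.  They do
not converge to *zero* difference: both estimators difference
near-equal quantities whose leading α² coefficients differ by the τ
substitution, leaving a finite limiting gap of order (R1·TR)² relative
(≈0.4% in R1 for R1·TR = 0.026).  The difference does vanish when TR is
scaled down together with the angles.  The test suite asserts exactly
this behavior.

## Bias simulation

`run_bias_sweep` generates noiseless exact-Ernst signals for a scenario
(protocol + ground-truth tissue + ft grid) and records each closed
form's percent error against truth — pure estimator bias, fully
deterministic.  Built-in scenarios:

| scenario | R1 (s⁻¹) | TR (ms) | nominal flips | ft range |
|---|---|---|---|---|
| `invivo` | 0.82 | 31.6 / 31.6 | 5° / 27° | 0.45 – 1.35 |
| `postmortem` | 2.0 | 70 / 70 | 18° / 84° | 0.60 – 1.10 |

A = 1 in both, so relative and absolute A errors coincide.  The default
ft grid step is 0.005 — finer than the 5% bins used for experimental
histograms — so the bias maximum is resolved smoothly.

`noise_propagation` adds zero-mean Gaussian noise to the signals and
reports the Monte-Carlo standard deviation of valid estimates per ft.
Conventions (fixed because no external convention exists for them):
SNR is defined against the noiseless PD-weighted signal at ft = 1, the
same noise sd is applied to every volume, and the noise is Gaussian on
magnitude signals — the high-SNR limit of Rician noise, which keeps the
first-order analytic prediction exact.  `delta_method_sd` provides that
prediction from central finite-difference gradients of the closed forms
(step 1e−6 relative).  Default 1000 replicates per grid point; the
Monte-Carlo sd then carries ≈2% relative sampling error.

A consequence worth knowing: at the very large angles of the postmortem
protocol the small-angle estimator's R1 standard deviation is genuinely
*smaller* than the Padé estimator's (analytic ratio falling to ≈0.79 at
ft = 1.10) — a bias-variance trade, not an artifact.  Over the in vivo
range the two are equal to within ≈3%.

## Synthetic phantom

`generate_phantom` builds a 3-D digital phantom: ellipsoidal tissue
compartments on a zero-signal background, a smooth single-lobe Gaussian
ft field min-max rescaled to an exact target span, weighted volumes
computed voxelwise by the exact Ernst equation, and optional i.i.d.
Gaussian noise (seeded, bit-reproducible).  The default is a 64³ grid
at 1 mm: a "GM" shell (R1 = 0.55 s⁻¹ — an arbitrary but plausible
cortical value) around a "WM" core (R1 = 0.82 s⁻¹), A = 1 in both, ft
spanning the in vivo range with its lobe off-center, mimicking the
center-bright transmit pattern of a head coil.  The automatic noise
level (`noise_sd=None`) gives SNR 100 in the WM PD-weighted signal.

The ft field is also stored block-averaged by an integer factor
(default 4), emulating the much coarser resolution at which transmit
maps are acquired.  Coordinate conventions: scaling-only affine,
0-based indices, world = index·voxel_size; the coarse grid's affine
carries the half-block offset that keeps coarse and fine voxel centers
aligned in world space.  `resample_ft_to_map_space` interpolates
trilinearly in world coordinates with edge clamping outside the coarse
support; trilinear interpolation is exact for affine fields, and the
phantom round-trip error decreases monotonically as the downsampling
factor approaches 1.

What the phantom does *not* emulate: realistic anatomy, multi-echo R2*
decay, receive-field modulation, Rician noise, motion, or
reconstruction effects.  Passing phantom tests therefore demonstrates
correctness of the estimator algebra, the resampling geometry and the
pipeline plumbing — not robustness to those real-data effects.

## Map pipeline

`compute_maps` applies any estimator voxelwise to weighted NIfTI
volumes plus an ft map (resampled if coarser), under an optional mask.
It refuses misaligned inputs (shape or affine mismatch) rather than
resampling weighted data — registration is upstream.  Inputs are
assumed TE-matched or TE = 0-extrapolated; no R2* or receive-bias
correction is applied, so the A map retains receive-field modulation.
Outputs are float32 NIfTI maps (NaN where invalid) with a JSON
provenance sidecar (method, protocol, software version, input
checksums, validity summary).  The pipeline adds I/O and masking only;
per-voxel arithmetic is bit-identical to the estimators module (tested
by spot checks), and invalid-voxel counts are conserved:
n_total = n_valid + Σ invalid-by-cause.

## Error statistics

* **ft-binned errors** — left-closed right-open uniform bins (final bin
  closed); per bin the median and the 2.5th–97.5th percentile span of
  the within-bin voxel errors.  The "95% interval" is sample spread,
  not a standard error of the median — it describes the voxel
  distribution.  Percentiles interpolate linearly between order
  statistics.
* **Inclusion range** — central-coverage quantiles of ft outward-rounded
  to a step (floor/ceil), the rule used to avoid sparsely populated
  tail bins.
* **2-D densities** — plain joint histograms of (ft, error) with dropped
  out-of-range counts; marginals agree exactly with the 1-D binning.
* **WCV** — within-participant coefficient of variation over test-retest
  pairs: WCV(%) = 100·√((1/N) Σᵢ dᵢ²/(2mᵢ²)) with dᵢ the pair
  difference and mᵢ the pair mean, i.e. the standard paired
  within-subject CV with the two-point variance d²/2.  Exactly
  invariant under common rescaling.  Other WCV estimators exist in the
  reproducibility literature; this form is the documented choice here.

## Problem sizes and defaults

Validation runs use: 181-point ft grids (step 0.005) for bias sweeps,
1000 Monte-Carlo replicates per ft for noise propagation, a 64³ phantom
for map-level round trips and 32³ for unit-level checks, and 1000
randomized draws for inversion properties — sizes at which every
quantity of interest is resolved well below its assertion tolerance
while the full suite runs in seconds.

## Known limitations

* Imperfect spoiling, magnetization transfer, and myelin-water
  compartment effects are outside the signal model; all grow with flip
  angle and would add bias the Padé inversion does not remove.
* Gaussian (not Rician) noise throughout; conclusions about noise
  propagation apply in the high-SNR regime.
* The exact equal-TR inversion and the WCV formula follow standard
  forms chosen here; both are validated internally (round trips,
  simulation recovery) rather than against an external reference
  implementation.
* ft-map inaccuracy itself (as opposed to its spatial resolution) is
  not modeled; the phantom's coarse map is a downsampled truth.
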