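# Methods

## The augmentation model

A simulated measurement is `Y = s_i + f_1 + … + f_M`, where `s_i` is an
experimental seed spectrum and each `f_k` is an independent draw from a
variability source. A source is a set of calibration difference vectors
`d_j` (j = 1…m) on the same spectral axis as the seeds, in one of two
forms:

* **mean-centered** — deviations `d_j = u_j − ū` of repeated measurements
  of one material (QC pools, water blanks, or, pooled per subject, the
  visits of held-out donors). Column sums are zero by construction and this
  is enforced as a type invariant.
* **paired** — `d_j = u_j − v_j` between index-paired measurements of the
  same sample under two conditions (e.g. serum minus plasma of the same
  blood draw).

A draw is `f = shift + (λ/√m) Σ_j c_j d̃_j` with `c_j ~ N(0,1)` i.i.d. per
generated measurement and per source. The `1/√m` prefactor makes the
injected covariance at `λ = 1` equal to the empirical second moment
`(1/m) Σ d̃_j d̃_jᵀ`, so `λ` reads as a multiple of the observed
variability and variance stress tests are pure `λ` sweeps. For paired
sources an optional shift moves seeds along the mean difference `d̄`:
`shift = α·d̄` with `α` fixed, or `α ~ Uniform(0,1)` per draw, in which case
the residual differences are centered (`d̃_j = d_j − d̄`) so the stochastic
part stays zero-mean. The uniform mode produces training spectra that
resemble mixtures between the two conditions — the default for specimen
transfer, where the test specimen is one endpoint of the mixture axis; the
deterministic `α = 1` variant transports seeds fully to the other
condition. Closed forms for the injected covariance and per-channel
standard deviation are exposed (`VariabilitySource.injected_covariance`,
`injected_std`) and are the oracles for the Monte-Carlo tests.

Draw order inside a cohort (standard normals first, then mixture
coefficients, sources in listed order, rows seed-major) is fixed and part
of the reproducibility contract: one `rng_seed` in `SimulationConfig`
reproduces a cohort bit-identically. With all scales at zero and no shift,
generated rows are bit-exact copies of the seeds.

Degenerate all-zero difference sets are allowed (they inject nothing) and
emit a warning.

## Classification harness

* **PCA** is fitted on training rows only, via eigendecomposition of the
  channel covariance; the component count is the smallest number reaching
  `variance_kept` (default 0.99) of total variance, capped at `n_train − 1`.
  Component signs are fixed (largest-magnitude loading positive) for
  determinism.
* **Multiclass identification**: with exactly one training row per class a
  1-nearest-neighbor rule in PCA space is used (Euclidean distance, ties to
  the lowest training-row index); otherwise a linear discriminant with
  pooled within-class covariance, empirical priors, and a ridge of
  `1e-8 ×` the mean covariance diagonal (absolute floor `1e-12` for exactly
  degenerate scatter, e.g. duplicated rows at `λ = 0`).
* **Binary scoring**: ridge-penalized logistic regression
  (scikit-learn lbfgs, tolerance 1e-10) on channels standardized with
  training statistics; `ridge_strength` defaults to 1.0. AUC uses the
  midrank convention.
* **Log trend**: OLS of accuracy on log2(population size); with constant
  accuracies the slope is 0 and R² is defined as 0.

Models are frozen after fitting; prediction never adapts to test data.

## Synthetic scenario generator

The generator emulates the statistical structure of longitudinal blood-IR
studies, not their physics:

* **Spectra** are sums of 12 Gaussian bands on a 1000–3000 cm⁻¹ axis
  (500 channels), with positions echoing the amide I/II, lipid-ester,
  carbohydrate and C–H stretch regions and amplitudes in [0.1, 1.0] a.u.
* **Biology is low-rank**: person effects and visit-to-visit random walks
  act in a 4-dimensional latent factor space mapped to band log-amplitudes
  through a per-scenario loading matrix. This mirrors the fact that blood
  composition varies along a few physiological axes, and it is what makes
  identification accuracy decline steadily with population size (crowding
  in a low-dimensional space). Defaults: between-person scale 0.18,
  within-person step 0.035 per visit.
* **Instrument and handling**: each measurement gets a smooth session
  drift (random cubic plus low-pass-filtered noise, scale 0.015 a.u.),
  multiplicative gain `N(1, 0.01)` and white channel noise (0.004 a.u.).
  Two instrument states exist: training visits are measured under state A,
  test visits under state B, which adds one fixed smooth offset
  (scale 0.015) drawn per scenario. Clinical-study protocols add per-study
  smooth offsets (scale 0.02, 3 studies; study 0 is the scenario's own).
* **Calibration sets** never involve study subjects: 12 held-out donors ×
  6 visits cycling through studies and states (longitudinal set), 48 QC
  measurements of a constant pooled material under both states, 48 blank
  (noise-only) replicates, and optionally paired plasma/serum measurements
  of further held-out donors. The four standard sources derived from them:
  within-person (per-subject mean-centered longitudinal deviations),
  study-protocol (mean-centered per-study means), QC drift, and replicate
  noise.
* **Specimen pairs**: serum-like spectra are the attenuated (×0.97)
  plasma spectrum plus a fixed five-band offset (peak 0.10 a.u.) in the
  carboxylate/protein regions; pair members share biology and session.
* **Case–control**: cases receive fixed per-band amplitude deltas
  (peak 0.0135 a.u., well below between-person scatter); train and test
  cohorts use disjoint subjects and different instrument states.

Magnitudes were calibrated once — so that experimental-only single-baseline
identification of 32 individuals lands mid-range (≈0.4–0.7), leaving
measurable headroom — and then frozen as the package defaults; all
benchmark results are reported on these frozen settings. What the generator
does **not** emulate: Mie/atmospheric scatter, water-vapor lines, detector
nonlinearity, batch-correlated label noise, or any fitted resemblance to
real cohort spectra. Passing benchmarks therefore demonstrates that the
method recovers the variability structure it is given under this model, not
performance on any real cohort.

## Experiment protocols and numerical choices

Every experiment evaluates all its conditions on one shared test set and
records a hash of that test set; per-condition RNG seeds derive from one
root seed through a seed sequence, so a report is reproducible from its
config snapshot. A leakage guard rejects scenarios whose calibration
subjects overlap study subjects.

Domain-agnostic augmentation baselines (additive white noise,
multiplicative gain, baseline offset+slope, within-class convex
interpolation) are matched to the same total injected variance (trace of
the injected covariance summed over sources) as the calibration-informed
augmentation; offset and slope split the trace equally.

Benchmark problem sizes are the package's frozen choices: 32 individuals ×
4 visits with 1,000 simulated measurements per seed for identification;
population scans use doubling sizes 2–128 from a 128-individual scenario
with 5 subset repeats and 200 measurements per seed (the trend statistic is
unchanged by the smaller per-seed count); specimen transfer uses 24
calibration pairs and 500 per seed; the case–control curve uses a
220-subject pool, training sizes 25–200, 3 stratified repeats, 100 per
seed. Dispersion across scenario seeds is reported as mean over an explicit
seed list (benchmarks use 5 seeds in the test suite, 3 in the acceptance
script).

## Known limitations

* Characterized variability must actually span the test-time shifts; a
  drift pattern absent from every calibration set cannot be injected.
* The Gaussian-coefficient aggregation reproduces second-order structure
  only; heavier-tailed or nonlinear measurement artifacts are approximated
  by their covariance.
* Axes are never resampled: datasets on different wavenumber grids are an
  error by design.
* The file dialect stores spectra densely as text; it is meant for
  benchmark-scale data, not production archives.
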