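# Methods

This note documents the models and numerical procedures implemented in
`neurocrit`, the assumptions behind them, what the synthetic-data
generators do and do not emulate, and the design choices made where the
methodology left the design open.

## Biomarkers

### Band-pass filtering and envelope extraction

All narrow-band analyses use a zero-phase linear-phase FIR band-pass
(Hamming-window design, 1 Hz transition width, ~3.3·fs taps), applied by
convolution with exact group-delay compensation so envelopes are not
phase-distorted. The amplitude envelope is the magnitude of the analytic
signal (Hilbert transform), the standard choice for narrow-band
long-range-temporal-correlation work. Edge samples equal to the filter
half-length (~1.65 s at 250 Hz) are contaminated by the convolution
boundary and are trimmed before any envelope statistic.

The default analysis bands are the two log-spaced alpha sub-bands
8.3–10.5 and 10.5–13.4 Hz; the individualized-alpha variant instead
splits [PAF − 2, PAF + 2] Hz into its two halves, computing each biomarker
per half-band.

### Detrended fluctuation analysis

Given an envelope A, the profile S(t) = Σ_{k≤t}(A(k) − ⟨A⟩) is split,
for each of 10 log-spaced window sizes over a fit range (default
2–20 s), into windows with 50% internal overlap; each window is linearly
detrended (DFA-1) and the fluctuation for that size is the **mean across
windows of the per-window RMS**. The scaling exponent is the least-squares
slope of log₁₀ fluctuation versus log₁₀ size. The lower fit bound of 2 s
stays more than an order of magnitude above the envelope correlation
time imposed by the 8.3 Hz band edge, limiting filter-induced bias; the
fit range is configurable for sensitivity analyses.

The estimator validates cleanly: raw white noise gives 0.489 ± 0.02 and
exact fractional Gaussian noise (fGn) with Hurst 0.6/0.75/0.8 gives
0.604/0.759/0.811 (20 seeds, 300 s each). One property worth knowing:
the Hilbert envelope of *band-passed* white noise carries a slowly
decaying (sinc²-tail) autocorrelation from the band edges, so its DFA
exponent over 2–20 s is ≈ 0.56 — below the 0.6 validity gate but
distinctly above the 0.5 of unfiltered noise. This is intrinsic envelope
physics (an ideal brick-wall band-pass reproduces it), not estimator
bias, and it is the reason the fE/I validity gate is placed at 0.6
rather than 0.5.

### Functional E/I ratio

fE/I follows the seven-step procedure: band-pass, envelope A, profile S,
5-s windows at 80% overlap, per-window division of the profile segment
by that window's mean envelope, linear detrending, per-window standard
deviation (the normalized fluctuation nF), and finally
fE/I = 1 − Pearson r(amplitude, nF) across windows. Windows with zero
mean amplitude are dropped pairwise. The result is flagged invalid — and
fE/I reported as NaN — when the full-signal envelope DFA exponent does
not exceed the gate (default 0.6; 0.55 supported as a sensitivity
setting), when fewer than 10 windows survive, or when either series has
zero variance; a reason code distinguishes the cases. Gating is applied
per channel × band on the full-signal DFA, before any regional
averaging. By the Pearson bounds fE/I ∈ [0, 2], and fE/I + r = 1 holds
exactly; the whole statistic is invariant to positive rescaling of the
input signal.

### Spectral parameterization

Power spectra are estimated by Welch's method (4-s Hann segments, 50%
overlap, mean averaging; 0.25 Hz resolution, giving 17 bins across the
1–5 Hz aperiodic fit). The spectrum is decomposed on a log₁₀-power scale
into an aperiodic component offset − β·log₁₀f plus up to 6 Gaussian
peaks with FWHM constrained to [2, 12] Hz and minimum height 0.1 log₁₀
units. The fitter is self-contained: a robust aperiodic line fit
(re-anchored to the lower spectral envelope so peaks cannot drag the
slope), iterative peak extraction from the flattened residual, one joint
peak refit, aperiodic refit on the peak-subtracted spectrum, and a final
peak refit. Two configurations are exposed: the 1–5 Hz fit for the
criticality-relevant low-frequency exponent (fixed mode, no knee — the
range is too narrow to identify one, and the low-frequency regime below
the alpha peak is the regime of interest), and a 1–40 Hz fit from which
the PAF (largest detectable peak in 6–14 Hz) and its modeled height
above the aperiodic background are read. On noiseless model spectra the
fitter recovers β exactly; through Welch estimation on shaped noise the
1–5 Hz fit carries a small (+0.03) upward tendency from spectral leakage
at the steep low-frequency end, well inside the quoted ±0.1 recovery
tolerance.

## Synthetic data

### Oscillatory signals

One channel is built as env(t)·sin(2πf_α t + φ) + background/osc_snr.
The envelope derives from a single exact fGn process (circulant
embedding, so the theoretical DFA exponent equals the requested Hurst
exponent), band-limited below 2.8 Hz (FIR low-pass) so the oscillation's
sidebands stay inside the alpha band and clear of the 1–5 Hz aperiodic
fit range. The process is split into spectrally disjoint slow (periods
above the 5-s window scale) and fast components — independent by
Gaussianity — and combined as

    env = L(slow) · (1 + d·gain·fast),   L(x) = 1 + d·x + (d·x)²/2,

with modulation depth d = 0.3. The quadratic (exponential-to-second-
order) level makes the level's relative within-window fluctuation
independent of the level, while truncating the higher-order convexity of
a full exponential that would couple window-mean amplitude to
within-window variance: with gain ≡ 1 the windowed amplitude and
normalized fluctuation are uncorrelated by construction (measured
r = +0.000 ± 0.008 over 200 realizations on the true envelope, +0.006
through the full band-pass/Hilbert chain), i.e. the zero-coupling signal
is a critical-state surrogate with fE/I = 1 in expectation. The coupling
control κ applies gain = 1 + κ·z_block per 5-s generator block (z_block
the standardized block level), making fluctuations relatively larger in
high-amplitude stretches for κ > 0 (fE/I < 1) and smaller for κ < 0
(fE/I > 1) without changing block means, hence mean power — it
manipulates exactly the covariance fE/I measures. The sign law
sign(1 − fE/I) = sign(κ) holds in every one of 20 seeds for |κ| ≥ 0.5.
The background is Gaussian noise spectrally shaped to f^(−β), scaled so
the oscillation-to-background RMS ratio equals osc_snr.

Defaults: fs = 250 Hz, 194 s duration (a realistic clean-segment length
for pediatric resting EEG, making window counts representative),
f_α = 10 Hz, Hurst 0.75, β = 1.46, osc_snr = 1.

What the generator does **not** emulate: artifacts (blinks, muscle,
electrode pops), non-stationary state changes, multichannel spatial
correlation (volume conduction), or biophysical network dynamics. A
passing test therefore shows the *estimators* behave correctly on
signals with known statistical structure, not that real EEG meets that
structure.

### Cohorts

Subjects draw age ~ uniform(6, 19) years, sex ~ Bernoulli(1/2), and
IQ ~ normal(111, 13) truncated to [71, 145] by rejection sampling
(simple and exact). Each (network, hemisphere[, band]) cell gets

    value = b0 + effect·(IQ − IQ̄)·(rank − 4) + subject intercept + noise

with configurable interaction size, random-intercept SD and residual SD
(defaults 0.1 each, chosen so the interaction tests operate at realistic
signal-to-noise), plus an `extra_effect` hook for injecting nonlinear
structure. Effect sizes are chosen for testability — the empirical
heterogeneity of real fE/I has no published generative model.

The pipeline's signal-level simulator couples the two layers: per-channel
coupling κ = 0.35·z_IQ·(rank − 4)/3 and background exponent
β = 1.46 − 0.15·z_IQ·(rank − 4)/3, so high-IQ subjects drift toward
lower fE/I and flatter spectra in high-rank association networks — the
moderation structure the statistical stage is designed to detect.

## Network tables

Channels map to the seven canonical resting-state networks ranked 1–7
along the sensorimotor–association axis: visual 1, somatomotor 2, dorsal
attention 3, salience/ventral attention 4, limbic 5, control 6,
default 7, with ranks 1–3 grouped as sensorimotor and 4–7 as
association. This rank assignment is a declared, editable convention
(the map is a CSV); the bundled default places a 10-20 montage onto the
networks with midline electrodes excluded. Aggregation means ignore
missing (gated) members; a cell with no valid member is missing. The
record-count identities hold exactly on complete data: 7 × 2 × N network
records per single-band biomarker, 2 × 2 × N after hierarchy collapse,
doubled per extra band.

Missing fE/I cells can be imputed by a chained random-forest imputer
(wide pivot per subject; each incomplete cell regressed on age, sex, IQ
and the sibling cells; iterated until the mean out-of-bag error stops
improving). It is deliberately a simplified chained regressor, seeded
and deterministic, with a flagged mean-imputation fallback for
degenerate designs; imputation is off by default and all sensitivity
paths run without it.

## Statistical models

**Region-level OLS**: per-subject region means (hemispheres and bands
collapsed) regressed on IQ with age and sex as covariates of no
interest; the standardized IQ coefficient is reported alongside the raw
one.

**Multilevel models**: REML linear mixed models (statsmodels MixedLM)
with random subject intercepts; fixed effects age, sex, hemisphere,
(band,) and hierarchy × IQ (two-level factor at region level) or
rank × IQ (continuous at network level), IQ and rank centered at their
sample means. Denominator degrees of freedom use the Satterthwaite
approximation, computed from the closed-form REML likelihood of the
random-intercept model: df = 2·Var(β̂ⱼ)²/(g′Ag) with g the finite-
difference gradient of Var(β̂ⱼ) in the log-variance parameters and A the
inverse observed REML information. The implementation matches lmerTest
to four decimals on shared fixtures. A variance estimate at the zero
boundary triggers a labeled normal-approximation fallback. Because the
default optimizer occasionally stops at the τ² = 0 boundary when the
optimum is interior, boundary solutions are cross-checked against a
derivative-free refit and the higher-likelihood fit kept.

**Johnson–Neyman**: the simple slope of the focal predictor at each
moderator value m is β_focal + m·β_int with variance from the
coefficient covariance; the significance region is where |t| exceeds the
critical value at α = 0.05 with the focal term's denominator df. The
grid construction agrees with brute-force recentered refits to 1e−6.

**GAMMs**: Gaussian additive models with parametric linear terms (all
main effects and interactions of age, rank/hierarchy, IQ, plus sex,
hemisphere, band), tensor-product P-spline smooths (cubic B-splines,
k = 4 per margin, second-order difference penalties, sum-to-zero
constrained; hierarchy enters as a by-factor giving one smooth per
region, rank as a continuous margin), and subject random intercepts as
an identity-penalized block. Smoothing parameters are selected by REML
via the generalized Fellner–Schall update — the multiplicative form
λⱼ ← λⱼ·σ̂²·[tr(S_λ⁻Sⱼ) − tr((X′X+S_λ)⁻¹Sⱼ)]/(β̂′Sⱼβ̂), whose fixed
point is the REML stationarity condition — iterated to convergence with
λ clipped to [1e−7, 1e7]. `select=True` (default) adds a null-space
penalty per smooth so purely linear structure can shrink to ~0 effective
df, in which case the duplicated linear directions are absorbed by the
unpenalized parametric copy. Inference uses the Bayesian posterior
covariance σ²(X′X+S)⁻¹: t-tests on n − edf_total residual df for
parametric terms, and approximate Wald F statistics on rank-truncated
covariance blocks for smooths. Fitted smooth edf, F, σ² and fitted
values track mgcv (method="REML", select=TRUE) on shared fixtures; the
smooth-term p-values are a simpler approximation than mgcv's and are
used for qualitative significance patterns, not exact replication.
Prediction surfaces are exported at IQ = mean − SD / mean / mean + SD
over an age grid.

**Subgroup and rank tests**: Welch two-sample t-tests comparing high-IQ
(≥ mean + SD) versus low-IQ (≤ mean − SD) subjects on per-subject region
means; Wilcoxon rank-sum tests (midranks for ties, exact null
distribution up to n = 20 per group, otherwise tie-corrected normal
approximation) for age-group contrasts. Bonferroni correction uses
p_adj = min(1, m·p) with m = the number of tested fixed plus smooth
effects counted from the fitted model formula, and m is reported with
every result.

Calibration, measured by simulation at reduced n (32 subjects, 500 null
replicates): the empirical size of the nominal-0.05 interaction tests
lies in [0.03, 0.08] for both the multilevel and the GAMM parametric
route, and the multilevel rank × IQ interaction estimate at n = 128 has
|bias| < 10% of truth over 50 replicates.

## Pipeline

A single YAML-loadable config drives signals → biomarkers → tables →
models. Randomness fans out from one seed through counter-based
substreams per (subject, channel), so results are independent of
iteration order; reruns with the same config and seed produce
byte-identical CSVs. Per-subject failures (unreadable or corrupt files,
too-short signals) are isolated, logged, and reduce n without aborting
the run. The sensitivity sweep re-runs the fE/I stage and the headline
network-level interaction over a window (3–6 s) × overlap (75–85%) grid
— bounds outside which the windowing itself is unreliable — and reports
the interaction's sign and (Bonferroni-adjusted) significance per cell.
The bundled demo (32 subjects × 19 channels × 180 s) completes in about
a minute on one CPU; problem sizes in the test suite are scaled to keep
each stage's check in the seconds range.

## Known limitations

- The GAMM smooth-term test is an approximate Wald construction, looser
  than mgcv's; parametric-term inference is the calibrated route.
- The Satterthwaite machinery covers the single random-intercept
  structure used here, not general random-effect designs.
- The EDF writer targets standard 16-bit EDF with 1-s records and
  integer sampling rates — sufficient for round-tripping synthetic
  signals, not a general-purpose EDF library.
- The spectral fitter has no knee mode; spectra with a genuine knee
  inside the fit range would bias β.
- fE/I values are estimation-noisy at realistic durations (SD ≈ 0.11
  per 300-s signal across seeds); single-signal values should be read
  accordingly.
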