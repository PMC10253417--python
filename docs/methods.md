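# Methods

## Problem setting

Subjective tinnitus patients report their distress on the Tinnitus
Handicap Inventory (THI, 0–100); a cut-off of 48 separates mild/moderate
from severe/catastrophic distress, with study inclusion requiring
THI ≥ 18.  The package asks whether tinnitus-related distress can be
classified from auditory evoked potentials — the auditory brainstem
response (ABR, waves I–V inside ~10 ms after a click) and the auditory
middle latency response (AMLR, troughs Na/Nb and peaks Pa/Pb at
~12–60 ms) — alone or together with clinical covariates.  Each patient
contributes one waveform per ear per subtype, and ears are the
classification instances for waveform-based models.

## Synthetic cohort generator

No public dataset exists for this problem, so every stage is exercised on
synthetic cohorts whose statistical structure matches what the analysis
assumes.

A waveform is a sum of Gaussian bumps plus additive noise:
`x(t) = Σ_w A_w exp(−(t − τ_w)² / 2σ_w²) + ε(t)`.

Defaults (configuration values, not code constants):

| wave | latency (ms) | amplitude (µV) | width (ms) |
|------|-------------|----------------|-----------|
| I / II / III / IV / V | 1.6 / 2.8 / 3.9 / 4.9 / 5.6 | .30 / .12 / .30 / .12 / .45 | 0.25 |
| Na / Pa / Nb / Pb | 18 / 30 / 42 / 55 | −0.8 / +1.0 / −0.7 / +0.6 | 4.0 |

ABR records: 450 samples at 30 kHz (15 ms window); AMLR: 450 samples at
3 kHz (150 ms).  Waves II and IV are generated but never annotated,
mirroring clinical reporting of I, III and V.  Noise is white Gaussian,
default SD 0.05 µV (a realistic residual after response averaging); a 1/f
option exists.  Between-ear biological variability is truncated-normal
jitter (±2.5 SD) on latency (0.10 ms ABR, 1.5 ms AMLR) and amplitude
(0.05 µV ABR, 0.15 µV AMLR); the truncation reflects that anatomy bounds
wave timing — an untruncated Gaussian would, across the ~10⁴ draws of a
cohort, occasionally place a wave outside its physiological window.

Group effects are configurable high-minus-low shifts per wave.  Defaults
follow the reported directionality: high-distress ABR waves arrive
slightly earlier (III, V: −0.06 ms) with larger I and V amplitudes
(+0.04 µV); high-distress AMLR waves arrive later (Pa/Nb/Pb: +1.0 ms)
with larger absolute amplitudes for all four waves.  Wave I latency and
Na latency carry no effect by default, so the feature gate always has
true-null metrics to reject.  The high-distress fraction defaults to 0.46; THI scores are
drawn uniformly within the group's range so label and cut-off coincide
exactly.

The clinical table has 33 covariates (15 named + 18 documented fillers,
mixed numeric/categorical with integer level codes).  Four audiological
variables (hearing loss, tinnitus pitch match, matching loudness, minimal
masking level) are generated per ear plus a per-ear audiogram; covariates
named in `clinical_effects` receive a group mean shift (defaults: GUF +6,
hearing loss +4, hearing loss at 6 kHz +5, age +3, minimal masking level
+4); `missing_rate` (default 5%) of feature cells are blanked.

**What the generator does not model:** between-ear correlation within a
patient (each ear is drawn independently, so ear-level tests are exactly
calibrated but twin-ear leakage cannot arise in the data itself — the
grouped cross-validation folds guard against it anyway), non-Gaussian
wave shapes, latency–amplitude dependence, covariate correlation
structure, and any realistic missingness mechanism (cells are blanked
completely at random).  Passing tests therefore demonstrate correctness
of the machinery under the assumed structure, not clinical performance on
real recordings.

## Wave annotation

Each wave is the largest strict local extremum of its polarity inside a
configurable latency window (defaults: I 1.0–2.5, III 3.0–4.8,
V 4.8–7.5 ms; Na 12–25, Pa 25–40, Nb 35–52, Pb 45–80 ms), searched
greedily in canonical order with each window truncated to start after the
previous found wave.  Preferring the largest *local extremum* over the
raw window maximum matters: the leading edge of a later wave entering
through the window boundary is a monotone ramp there and must never
masquerade as a wave.  Plateaus annotate at their earliest sample; a
window with no strict local extremum of the right polarity reports
`found = False` (flat or monotone segments yield no annotation).
Latency is the extremum sample index converted to ms; amplitude is the
signed signal value in µV.  An optional zero-phase low-pass (off by
default) can precede detection on noisy input.

## Time-domain statistics

Ears are grouped at THI ≥ 48.  Per metric (latency and amplitude per
wave; AMLR amplitudes compared as absolute values, ABR signed): Levene's
test (centre = mean) gates between the pooled-variance Student t-test
(Levene p ≥ 0.05) and Welch's t-test; Cohen's d uses the pooled SD on the
Student branch and the root-mean-square SD on the Welch branch; the mean
difference carries a 95% CI from the chosen test's degrees of freedom.
The statistic is oriented low-minus-high.  Metrics with p < 0.05 become
classifier features — deliberately uncorrected for multiplicity (a Holm
option exists for sensitivity analysis).  Normality is assessed by QQ
plot export only: analytic normality tests at several hundred waveforms
reject for immaterial departures.  Subgroup descriptives stratify ears by
gender × hearing class × THI group (12 strata).  Hearing classes come
from the pure-tone average with contiguous half-open bins (≤ 20 normal,
(20, 60] mild, > 60 severe) — the conventional integer bins [0–20],
[21–60], > 61 leave non-integer averages in (20, 21) and (60, 61)
unassigned, so the half-open repair closes the gaps while agreeing with
the original bins on integers.

## Wavelet scattering transform

Second-order time scattering: `S0 = |x∗φ|`, `S1 = |x∗ψ_λ1|∗φ`,
`S2 = ||x∗ψ_λ1|∗ψ_λ2|∗φ`, with analytic Morlet-type wavelets ψ and a
Gaussian scaling filter φ of time support equal to the invariance scale
T.  Two filter banks with quality factors (Q1, Q2) = (8, 1) by default.
Study configurations: ABR — 30 kHz, 450 samples, T = 6 ms; AMLR — 3 kHz,
420 samples (records truncated from 450 as an explicit, logged
preprocessing step), T = 81 ms.

Filter-bank convention (four dimensionless constants, frozen after a
one-off calibration so the two study configurations produce exactly
40 paths × 15 windows and 65 paths × 7 windows):

* φ is Gaussian with time-domain σ = T/4 (±2σ support = T).
* Centre frequencies fall geometrically by 2^(1/Q) from the mother
  frequency 0.125·(2^(1/Q)+1) cycles/sample until the wavelet design
  bandwidth reaches 1.1× the φ bandwidth; below that, wavelets are
  linearly spaced with that constant bandwidth down to 2.25 φ-bandwidths
  above DC.
* An order-2 path (λ1, λ2) is admitted when λ2 < 1.5× the design
  bandwidth of ψ_λ1 (the envelope |x∗ψ_λ1| carries no structure above its
  own bandwidth).
* Output hop = 2^(round(log2(T·fs)) − 2) — about four output samples per
  invariance scale, rounded to a power of two — giving ceil(N/hop)
  windows.

Rendered frequency responses are DC-corrected Gaussians (ψ̂(0) = 0) with
width 1.5× the design bandwidth in the geometric region and 1.0× in the
dense linear tail; each wavelet carries base amplitude √2 (a real
signal's Hermitian spectrum weights each analytic wavelet by ½ in the
frame sum, so √2 lets a lone wavelet saturate the bound) and a per-filter
gain equal to the inverse square root of the local Littlewood–Paley
density, followed by an exact global cap enforcing LP(f) ≤ 1 everywhere.
The cap makes the transform non-expansive (‖S(x) − S(y)‖₂ ≤ ‖x − y‖₂);
the per-filter normalisation keeps LP ≥ 0.5 across the wavelet-covered
band.  Convolutions run in the frequency domain on a
reflection-padded grid (next power of two ≥ 2N); outputs are restricted
to the original support before downsampling.  The modulus is applied to
S0 as well so the raw tensor is non-negative throughout and the log
transform (ln max(·, 10⁻¹²), floor configurable) is defined on every
path.  The log is applied before scale averaging by default (a flag
swaps the order; either convention is defensible and the choice is
recorded in the run log).
"Top two levels" in the energy-concentration check means orders 0 and 1
of the computed orders 0–2.

Scale averaging takes the arithmetic mean across windows per path: 40
features per ABR signal, 65 per AMLR, 105 concatenated.

## Clinical preparation and LASSO selection

Order of operations: impute (numeric → column mean over observed values,
categorical → column mode, ties to the smallest level, logged), then
aggregate the four ear-level audiological variables by tinnitus
laterality (bilateral → two-ear mean, unilateral → affected ear,
head-derived → mean over tinnitus-matched ears, falling back to the
two-ear mean when no match is flagged, logged) — imputing first
guarantees the laterality rule never meets a missing affected-ear value.
THI binarizes at 48; patients under the THI 18 floor are dropped with a
warning.

Selection: binomial LASSO on standardized covariates (one-hot
categoricals; standardization computed once on the full table — the
selection is a screening step, not a performance estimate, so
within-fold re-standardization would add noise without protecting
anything).  Per repeat, 10-fold stratified CV scores a 15-point penalty
grid by held-out deviance and takes the strongest penalty within one
standard error of the minimum; the repeat's nonzero pattern comes from a
refit on a random half of the patients; a covariate is selected when
nonzero in ≥ 50% of repeats (default 100).  The one-SE rule and the
half-sample refit are deliberate: the deviance-minimizing penalty with
full-data refits admits roughly a dozen spurious covariates out of 28 at
n = 500 and repeats differ only in fold shuffling, so majority voting
cannot prune them; with the one-SE penalty and half-sample refits the
false-selection count drops to ≤ 3 while every covariate with a ≥ 0.8 SD
group shift survives.  λ-min and full-data refits remain available as
flags.

## Classification benchmark

Seven families: LDA, linear/RBF/polynomial SVM (posterior probabilities
via Platt scaling on internal CV splits), Gaussian naive Bayes,
single-hidden-layer MLP, random forest (500 trees).  Default grids: SVM
cost {0.25, 0.5, 1, 2, 4}; RBF γ by the median pairwise-distance
heuristic ×{½, 1, 2}; polynomial degree {2, 3}; MLP hidden size
{3, 5, 7} × weight decay {0.01, 0.1}; forest split candidates
{√p − 1, √p, √p + 1}.  Evaluation: stratified 10-fold CV; per fold,
standardization fit on training data only, grid search by 3-fold inner
AUC, then trapezoidal ROC AUC on held-out posterior scores plus
sensitivity/specificity at the 0.5 posterior threshold (positive class =
high distress); the report averages fold metrics (a pooled-prediction
ROC is exported for plotting) and carries fold-level confusion counts and
Youden-optimal thresholds.  Ear-level models group the two ears of a
patient into the same fold; clinical-only models use patients as
instances.  The integrated feature set broadcasts the selected clinical
covariates to both ears next to the 65 AMLR scattering coefficients.

## Numerical choices and degenerate inputs

* Voltages in µV throughout; latencies in ms from stimulus onset at
  sample 0.
* Record serialisation uses shortest-round-trip decimal text: bit-exact
  float64 round trips in both XML and CSV.
* compare_metric with two constant identical samples returns t = 0,
  p = 1, d = 0; constant unequal samples return ±∞ and p = 0.
* An all-zero scattering tensor has undefined energy fractions (raises).
* Tie-breaks: annotation plateaus → earliest sample; imputation mode
  ties → smallest level; identical CV AUCs → first grid point.
* Determinism: every stochastic step (generator, fold shuffles, liblinear
  coordinate order, forest/MLP initialisation) is seeded from the single
  run seed; two runs with the same configuration produce byte-identical
  artifacts (the manifest hashes verify this).

## Problem sizes used in the test suite

The suite exercises the full pipeline at reduced but statistically
adequate sizes chosen as desk-scale defaults: cohorts of 24–250 patients
per test, 500 null replicates for gate calibration, 20 seeds for
effect-grid and selection-recovery runs, 200 signal pairs for the
non-expansiveness check, and singleton hyperparameter grids with
100-tree forests where a full grid search would add nothing to the
property under test.

## Known limitations

* The scattering convention reproduces the standard output shapes for
  the two AEP configurations, but its internal frequency grid is its
  own; coefficient *values* are not comparable across scattering
  implementations.
* The annotator is a windowed-extremum detector; it does not reproduce
  any specific published annotation algorithm and scores neither wave II
  nor IV, nor interpeak intervals.
* Clinical covariates are generated independently; selection behaviour
  under strong collinearity is untested.
* Classifier performance numbers on synthetic cohorts say nothing about
  performance on real patient data.
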