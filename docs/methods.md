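# Methods

## Problem and scope

`ehgpredict` implements an electrohysterogram (EHG) analysis pipeline for
term/preterm discrimination: per-channel feature extraction (linear,
non-linear, and entropy features), internal-parameter optimization of the
entropy estimators by class separability, and linear-discriminant
prediction models built over SMOTE-balanced data with genetic-algorithm
(GA) wrapper feature selection, evaluated on 30 shared stratified holdout
partitions.  The clinical reference data for this kind of analysis are the
Physionet term/preterm EHG databases (TPEHG DB, TPEHGT DS: three bipolar
abdominal channels S1–S3 at 20 Hz, ~30 min records, roughly 7:1
term:preterm imbalance).  Because those recordings cannot be redistributed,
the package ships a synthetic-EHG generator with known ground truth; every
stage is exercised against it.

## Signal model of the synthetic generator

Each channel of a generated record is

    x[n] = A · sin(2π f t[n] + φ0 + J[n]) + ε[n]

with a per-class amplitude `A`, center frequency `f`, a phase-jitter random
walk `J` whose per-sample standard deviation is `0.2·(1 − regularity)` rad,
and AR(1)-shaped Gaussian noise `ε` (pole 0.9, scaled to a per-class
standard deviation).  `regularity = 1` gives a pure periodic channel.
Obstetric covariates are drawn from plausible distributions (age
~ N(31, 4²) years, weight ~ N(70, 10²) kg, parity/abortions ~ small
Poisson, gestation week at recording uniform on [22, 37]); delivery falls
before week 37 iff the record is preterm-labelled.  Artifact intervals
(duration 5–60 s, Poisson rate 1 per record/channel by default) are
annotations only and exercise the exclusion logic.

Default class parameters — the package's study conditions — are:

| class   | osc freq | osc amp | noise sd (rel.) | regularity |
|---------|----------|---------|-----------------|------------|
| term    | 0.45 Hz  | 50 µV   | 4.5 µV (9%)     | 0.70       |
| preterm | 0.45 Hz  | 80 µV   | 0.8 µV (1%)     | 0.98       |

Why these values and not a milder contrast: bubble entropy at the high
embedding dimensions used for EHG (m = 23–26) is **non-monotonic** in both
phase jitter and relative noise on sinusoid-plus-noise signals — a weakly
jittered oscillation with ~5–10% noise maximizes it, while both the
nearly-clean and the heavily degraded regimes score lower.  A naive
"preterm slightly more regular" parameterization therefore inverts the
expected entropy ordering for BubbEn (and, through its frequency
sensitivity, for DispEn if the class center frequencies differ).  The
chosen conditions put the preterm class in the near-noise-free periodic
regime and the term class past the jitter peak, which makes *all five*
estimators read lower for preterm (rank-sum p < 0.05 at 30 + 30 records,
both bands) — the direction reported for real preterm EHG.  The class
spectral difference comes from jitter-induced broadening rather than a
center-frequency shift.

What the generator does **not** emulate: contraction bursts and quiescent
intervals, electrode/motion artifact morphology (synthetic artifacts are
annotations, not waveform corruptions), tocograms, inter-channel
correlation, and the amplitude non-stationarity of real EHG.  Tests passing
on this generator validate the pipeline's mechanics and directional
behavior, not clinical performance.

## Preprocessing

Each channel is band-pass filtered with a fifth-order Butterworth filter
applied forward and backward (zero phase; effective magnitude order 10) in
two bands: the whole EHG bandwidth WBW 0.1–4 Hz and fast wave high FWH
0.34–4 Hz.  Annotated artifact intervals (half-open, seconds; overlaps
merged) are excised *after* filtering, and the remaining segments are cut
into 120 s windows with 50% overlap; windows never span an excised region.
Per-window features are reduced to one value per record/channel/band by the
median over windows, with missing values (degenerate windows) dropped.
Edge transients of the forward–backward pass use scipy's short reflective
padding; at 2400-sample windows they are negligible.

## Feature inventory (46 per channel)

* **Linear (20):** peak-to-peak amplitude in WBW and FWH; from a Welch PSD
  (512-sample Hamming segments, 50% overlap) of the WBW window, restricted
  to 0.2–1 Hz where EHG energy concentrates: dominant frequencies DF1
  (0.2–1 Hz) and DF2 (0.34–1 Hz), mean frequency, deciles D1–D9, normalized
  subband energies (0.2–0.34 / 0.34–0.6 / 0.6–1 Hz), high/low energy ratio
  (0.34–1 over 0.2–0.34 Hz, capped at 10⁶ for empty denominators), the
  spectral moment ratio M₋₁/M₅ (Mₖ = Σ fᵏP(f)df; the moment orders are
  configurable), and time-domain Teager energy.  Sub-bands are selected on
  the PSD rather than by re-filtering, since all lie inside WBW.
* **Non-linear (16 = 8 × 2 bands):** Lempel–Ziv complexity, binary
  (median threshold) and 6-state (equal-width bins; equal-count optional),
  normalized as c·log_α(N)/N; time reversibility (third moment of lag-1
  increments, exactly antisymmetric under time reversal); Katz fractal
  dimension on the (i, x[i]) curve; Poincaré ellipse metrics SD1, SD2,
  SDRR, SD1/SD2 at lag 1 (sample variance, ddof = 1).
* **Entropy (10 = 5 × 2 bands):** sample, fuzzy, spectral, dispersion and
  bubble entropy, described below.
* **Obstetric (5, cohort-level):** age, parity, abortions, weight, week of
  gestation at recording.

Names serialize as `<Feature>_<Band>_<Channel>` (e.g. `App_FWH_S2`,
`KFD_WBW_S1`) or `<Feature>_<Channel>` for the single-band spectral
features.

## Entropy estimators

* **SampEn(m, r):** −ln(A/B) with B/A the template-pair match counts at
  lengths m and m+1 under Chebyshev distance, tolerance r·sd(window),
  self-matches excluded; both counts use the same N − m templates.  A = 0
  or B = 0 yields a missing value (the record median then ignores that
  window).
* **FuzEn(m, r, n, family):** per-vector mean removal, pairwise Chebyshev
  distances mapped to graded similarities (seven families; exponential
  μ = exp(−dⁿ/r) with the published optimum r = 0.0077, n = 3), value
  ln φ_m − ln φ_{m+1}.  The published membership widths presume roughly
  unit-variance input (mV-scale clinical traces), so the extraction layer
  z-scores each window before FuzEn; the estimator itself defaults to raw
  input.  The other six families' optimized (r, n) pairs are not published
  alongside the exponential one; they ship as documented, configurable
  placeholders.
* **SpEn:** Shannon entropy of the band-limited PSD normalized by
  ln(number of in-band bins) ∈ [0, 1]; the band is the analysis band
  itself (WBW or FWH).
* **DispEn(m, c, mapping):** samples mapped to classes 1…c (linear
  equal-width, normal CDF, tangent/log sigmoid of the z-scored signal, or
  equal-count sorting), overlapping m-length patterns counted, Shannon
  entropy of the pattern distribution in nats (unnormalized by default;
  ÷ m·ln c optional).
* **BubbEn(m):** per-vector bubble-sort swap counts (= inversion counts,
  counted pairwise with strict inequality) at embedding sizes m and m+1,
  order-2 Rényi entropy of each swap-count distribution, value
  (H_{m+1} − H_m)/ln((m+1)/(m−1)).

All estimators use time delay 1.  SampEn, BubbEn, DispEn and SpEn are
invariant under positive affine amplitude transforms; FuzEn is only when
extraction-layer normalization is on.

**Parameter sweeps.** Grids: SampEn m 2–5 × r 0.05–0.30 (step 0.05);
FuzEn m 2–5 × 7 membership families; DispEn m 2–5 × c 3–9 × 5 mappings,
constrained to cᵐ < window length; BubbEn m 2–40.  For each grid point the
record-level medians are compared between classes with the two-sided
Wilcoxon rank-sum test and the lowest p-value wins (ties broken by smaller
m, then smaller r or c, then mapping/membership list order).  The packaged
reference settings (`reference_params.py`) are the published per-
band/channel optima from this procedure on the Physionet cohorts, so
extraction runs without re-optimization.

## Prediction models

Six compositions: En_SFS (SampEn/FuzEn/SpEn, 18 features), En_ALL (all
five entropies, 30), Linear (+obstetric, 65), LNL (113), LEn_ALL (95),
LNLEn_ALL (143).  Missing feature values are median-imputed per column at
matrix-build time (logged).

* **SMOTE (k = 5):** the minority class is oversampled to the majority
  count; each synthetic row is x + u·(x_nn − x), u ~ U(0,1), x_nn one of
  the k nearest minority neighbors by Euclidean distance on z-scored
  features.  Following the study design being reproduced, balancing is
  applied to the whole table *before* partitioning.  This leaks synthetic
  neighbors of test rows into training and inflates test metrics; the
  clean variant (`smote_placement="train-only"`, SMOTE inside each
  training split) is provided and documented, but is not the default.
* **Partitions:** 30 independent stratified train/validation/test thirds
  (largest-remainder rounding for odd counts), drawn once and reused by
  every model so cross-model differences are attributable to features
  alone (enforced by a partition digest).
* **LDA:** pooled within-class covariance with diagonal shrinkage
  ε = 10⁻⁶·trace/dim, priors from training class frequencies, features
  z-scored with training statistics.  The discriminant score is continuous;
  preterm is the positive class for sensitivity/PPV/F1, and AUC integrates
  the ROC of the scores (trapezoidal).
* **Model comparison:** Friedman test across models per metric on the
  per-partition values, pairwise two-sided rank-sum tests, no multiplicity
  correction by default (Holm available).

## GA wrapper selection

Population size = genome length = the model's feature count N; real genes
in [0, 1] thresholded at 0.5 into a mask (arithmetic crossover is defined
on real genes; a pure-binary uniform-crossover mode exists).  Tournament
size 2, 2 elites, crossover probability 0.8, per-gene uniform mutation
probability 0.01, stall criterion 150 generations at tolerance 10⁻⁶, with
a safety cap (default 2000 generations).  Fitness = mean validation F1
(fraction) × (N − |mask|); empty masks score −∞; fitness values are cached
by mask.  Consequences worth knowing:

* The parsimony weight dominates once F1 saturates, so optimal masks are
  small; the all-features mask scores exactly 0.  On a 5-informative /
  45-noise table (effect 2.0) the GA discards every noise column but
  typically keeps only 2–3 informative ones, because those masks genuinely
  score highest under this fitness.  A multiplicative-penalty alternative
  exists behind a flag, never as default.
* At small N the prescribed population sizing makes the search fragile
  (pop = N = 8 leaves little diversity; with 2 elites and pop 2 it cannot
  search at all).  Roughly 1 random seed in 10 at N = 8 ends a few percent
  below the exhaustive optimum; `population_size` is overridable where
  that matters.

## Numerical and design choices

* Missing values are NaN throughout; medians drop them, matrix build
  imputes them, and degenerate ratios (SD2 = 0, zero in-band power) produce
  them rather than infinities.  The H/L ratio is capped instead, to keep a
  heavily used feature finite on degenerate synthetic inputs.
* Katz FD of a constant trace is 1.0 (a horizontal straight line under the
  (i, x[i]) curve definition), not a missing value.
* Rank-sum: exact enumeration when n ≤ 12 without ties, otherwise normal
  approximation with tie and continuity corrections; two identical samples
  give p = 1.  Friedman uses the tie-corrected SS form and supports k = 2.
* Windowed analysis sizes used by the test suite and acceptance script are
  scaled-down study conditions chosen once: 90–300 s records, 30–120 s
  windows, 30 + 30 direction cohorts, N = 8 for the exhaustive GA check.
  The direction cohort uses 300 s records so a single artifact interval
  rarely destroys every whole window of a record.
* Determinism: every stochastic stage takes an explicit seed; per-record
  and per-run seeds derive from a root seed via `SeedSequence`.

## Known limitations

* The synthetic signal family is a single jittered oscillation plus
  colored noise; conclusions about estimator behavior in regimes it does
  not reach (burst dynamics, non-stationary amplitude) need real data.
* WFDB input requires the optional `wfdb` package; the supported interchange
  format is the package's CSV dialect.
* Bubble entropy estimates at m ≈ 23–26 from 2400-sample windows carry
  substantial sampling noise (neighbouring m can differ by ~0.1–0.3 on
  white noise); record-level medians and group statistics absorb this, but
  single-window values should not be over-interpreted.
* Pre-partition SMOTE (the default, for fidelity) optimistically biases
  every test-split metric; use `train-only` placement for honest
  generalization estimates.
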