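# Methods

`neoncts` implements a highly comparative time-series analysis of neonatal
vital signs: many parameterized feature operations are applied to short
windows of heart rate (HR) and oxygen saturation (SpO2), the redundant
results are clustered down to a small representative set, and the
representatives feed constrained logistic models of death within the next
seven days. Because no patient data ships with the package, a synthetic
cohort generator defines the study conditions end to end.

## Data model and windowing

Monitors report HR (beats/min) and SpO2 (%) at 0.5 Hz. The analysis unit is
a non-overlapping 10-minute window of 300 samples on a fixed 2-second grid
anchored at the cohort epoch; day boundaries are fixed 86,400 s blocks from
that epoch (the alternative — admission-relative days — is equivalent here
because synthetic patients are admitted at t = 0). Timestamps off the grid
snap to the nearest slot, collisions keep the last value, and windows with
any empty slot are retained but flagged incomplete; they are excluded at
the feature-filtering stage, not at read time, so the audit trail records
them. Each window carries a binary label: 1 if the patient dies and the
death day falls within 0–6 days after the window's day (the half-open
7-day horizon [0, 7)), and a real `days_until_death` measured from the
window start to the end of the death day. In the outcomes file,
`death_day` is −1 for survivors (the `died` flag is authoritative).

## Synthetic cohort generator

The generator emulates the qualitative phenotypes of pre-mortem monitor
data, not physiologic truth. Per patient, HR windows are
baseline (N(140, 8²) bpm across patients)
+ slow sinusoidal wander (4 bpm, 1 h period)
+ stationary AR(1) noise (marginal SD 3 bpm, lag-2 s coefficient 0.95)
+ Poisson-arriving upward acceleration ramps (0.5/min, ~8 bpm, a linear
rise over 8–16 s creating runs of successive increases). SpO2 windows are
baseline (N(96, 1.5²)%, capped at 99.5)
+ AR(1) noise (SD 1%)
+ Poisson desaturation events (2/h, 3–15% deep, fast drop and slow
recovery), clipped to (0, 100].

Patients who die (3.4% of the cohort, a realistic all-cause NICU
mortality fraction)
switch to a *dying phase* for their final 7 recorded days: HR variability
and wander are scaled by `premortal_variability_factor` (default 0.5),
acceleration arrivals by `premortal_acceleration_factor` (0.5), transient
decelerations appear (3/h, ~25 bpm), and the SpO2 baseline drifts by
`premortal_spo2_drift_pct_per_day` (−2%/day) cumulatively across the phase.
Every effect is a config knob; `CohortConfig.null_effect()` switches all of
them off, making dying and surviving patients exactly exchangeable — the
null configuration is verified by a test showing the generator output is
bit-identical with and without the dying flag.

Stays are truncated-normal integers with mean 20 days (large NICU
cohorts of this kind average roughly three weeks of monitoring per
infant), which with a 3.4% death fraction and 7-day horizon yields a
sample-level event incidence of roughly 1.2% — rare events, as in
practice. Demographics are simple parametric draws:
gestational age truncated-normal on 24–42 weeks (mean 34.7 for survivors,
32.4 for non-survivors), birth weight linear in GA plus noise, 5-minute
Apgar lower among non-survivors, 43% female. By default the generator
emits 24 ten-minute windows per day spread across the day grid rather than
full 43,200-sample days; `windows_per_day=144` produces contiguous full
days for windowing tests. One RNG stream is spawned per patient from the
master seed, so cohorts are reproducible even if generation is
parallelized.

What the generator does *not* emulate: gestational-age-dependent signal
dynamics, apnea/bradycardia coupling between the two channels, monitor
artifacts and dropouts, oximeter averaging (an optional 4-sample moving
average approximates it, off by default), or any disease structure.
Passing the recovery tests therefore shows the pipeline can find planted
effects of this shape at realistic incidence — not that it would achieve
any particular performance on real NICU data.

## Operation catalog

An *operation* is an algorithm plus a concrete parameter setting plus one
named output; each operation becomes one feature column per signal. The
default catalog holds 120 operations per signal across eleven families:
distribution moments and quantiles; linear autocorrelation (lags 1, 2, 5,
10, 25) and third-order lag-1 moments; StatAv stationarity ratios (5 and
10 segments); symbolic transforms (successive increases and the nine
ordered difference-sign motif frequencies); sample entropy over the
12-operation grid m ∈ {1,2,3} × r ∈ {0.10, 0.15, 0.20, 0.25}·SD; OLS trend
(slope, intercept, residual SD); spectral band powers (LF 0.04–0.15 Hz,
HF 0.15–0.25 Hz, Nyquist 0.25 Hz at 0.5 Hz sampling, Parseval-exact
normalization); surprise over (groups, memory) ∈ {3,5} × {50,100};
a coupled random walk at coupling 0.1/0.5/1.0; Haar wavelet level energies
(first 256 samples, 4 levels); false nearest neighbours at embedding
dimensions 1–5; and the moving-threshold extreme-event model over four
(rate, decay) settings. Every spec serializes to JSON and rebuilds exactly
from its id string.

Numerical conventions that matter:

- **Successive increases** counts overlapping strict double increases;
  equal consecutive values (common in integer bpm) are "same", never
  increases. For a 300-sample symmetric random walk the expectation is
  298/4 = 74.5, because consecutive *increment signs* are independent; for
  i.i.d. values it would be 298/6 ≈ 49.7 — the tests pin the random-walk
  null, the value usually quoted rounded as 75 (300/0.5²).
- **Moving threshold** operates on |z| within the window; the threshold is
  tested before it is updated (q₁ = 1), raised multiplicatively by 1 + a
  on an event and decayed by 1 − b otherwise; summaries are over the n
  tested thresholds and event indices. Constant windows are missing.
- **Surprise** uses distribution memory (symbol frequencies in the
  trailing window, not transition counts) with Laplace add-one smoothing
  p̂ = (count + 1)/(m + groups); both mean(1/p̂) and mean(log 1/p̂) are
  emitted because either is a defensible summary of "1/p".
- **Sample entropy** is −ln(A/B) with Chebyshev-distance template matching,
  self-matches excluded, r = r_frac·SD; zero-match and constant windows
  return missing rather than ±∞ so filtering handles them uniformly. The
  production path counts all (m, r) matches in one numba pass with early
  exit; a matrix-based implementation is kept and asserted equal, and both
  are tested against an O(n²) brute-force oracle at 1e−12.
- **FNN** uses a delay-1 embedding under the Chebyshev norm (the distance
  ratio in the false-neighbour criterion is scale-invariant, so z-scoring
  is unnecessary); threshold 10.
- **Random walk**: w₁ = 0, wᵢ = wᵢ₋₁ + p·(xᵢ₋₁ − wᵢ₋₁) on the z-scored
  window, evaluated with an exact linear filter.

Operators are pure functions of the window values; any internal failure
records a missing value and never aborts a batch.

## Feature matrix, sampling, filtering, normalization

Feature extraction yields one row per (patient, day, window start) with
signal-qualified columns. Daily reduction either averages a day's windows
or keeps one uniformly chosen window per patient-day. The random choice
depends only on the sorted key set and the seed, so sampling windows
*before* extraction and sampling matrix rows *after* extraction select
identical records — this exactness is tested, and the pipeline exploits it
by featurizing only the sampled windows.

Filtering drops columns that are single-valued, contain non-finite
results, or have any missing value (threshold configurable, strict by
default), then drops rows with remaining missing cells; an audit lists
every removal with its reason. For clustering, columns are winsorized at
the 0.1%/99.9% quantiles (linear type-7 interpolation) and passed through
the outlier-robust sigmoid f(v) = 1/(1 + exp(−(v − median)/(IQR/1.349)))
followed by min–max rescaling to [0, 1]; 1.349 is the IQR of a standard
normal, so the scale behaves like a robust SD. Zero-IQR columns fall back
to 1.349·SD. For modeling, features are winsorized (and standardized for
conditioning) but not sigmoid-squashed; the winsorization/normalization
parameters are learned on training data only inside cross-validation.
Strict idempotence of *re-estimated* winsorization is impossible with
interpolated quantiles (clipping moves the extreme quantile); the
estimator form — clip with fit-time bounds — is idempotent and is what the
pipeline uses.

## Clustering to representatives

Each surviving column is discretized into ten equiprobable bins (stable
rank order breaks ties deterministically) and pairwise distances are
d = 1 − MI/√(H_a·H_b), the normalized mutual information — bounded in
[0, 1], symmetric, zero exactly for rank-identical columns, and defined as
1 when a margin has no entropy. k-medoids over this matrix uses k = 20 by
default (a study parameter, not auto-selected; clustering is joint over
both signals, with per-signal k = 10 available). Instances with at most
5,000 candidate medoid subsets are solved exactly by enumeration; larger
instances use PAM (greedy BUILD + best-improvement SWAP, deterministic
with ties broken by column order, cost non-increasing). The exact small
path exists because single-swap local search measurably misses the global
optimum on a few percent of tiny instances, which would poison oracle
comparisons; at study scale (230+ columns) PAM is the path exercised.

Each cluster is summarized either by its medoid or (default) by the member
with the largest |AUC − 0.5| against the mortality label, ties resolved in
favour of the medoid. A variance-explained diagnostic — the mean over
columns of the best squared Pearson correlation with any representative —
quantifies how much of the full matrix the representatives span.

## Risk models and evaluation

Candidates (the 20 representatives, optionally plus birth weight, GA, sex,
and 5-minute Apgar as never-dropped covariates) enter a maximum-likelihood
logistic regression fit by Newton/IRLS. Backward elimination repeatedly
drops the largest Wald p-value until five features remain; non-finite
p-values (collinearity) drop first, and quasi-separation triggers one
retry with a tiny ridge (1e−6) whose Wald covariance comes from the
penalized Hessian. Alternative selectors (AIC-greedy) sit behind the same
interface.

Discrimination is the pooled rank-based AUC of held-out predictions under
tenfold cross-validation grouped *and stratified* by patient: all of a
patient's days share a fold, and dying patients are spread round-robin
across folds. Stratification is load-bearing — with unstratified patient
folds, fold-specific intercepts track the training prevalence and pooling
the scores biases the null AUC to ~0.39; stratified folds restore the
chance level, as the null-calibration test verifies. The full recipe
(winsorize → standardize → select → fit) re-runs inside every training
fold. Horizon AUCs condition on time to death: for horizon d, positives
are samples with days-until-death in (d−1, d], samples closer to death are
excluded, and everything else is negative. The event-rate threshold flags
the top ⌈event rate · n⌉ predictions (stable order on ties), which makes
sensitivity and PPV identical by construction; lift is PPV divided by the
event rate.

## Pipeline, provenance, problem sizes

`run_pipeline` chains simulate → window/label → daily-sample → extract →
filter → cluster → select → fit → evaluate, and writes every artifact with
a SHA-256 digest into a local JSON manifest together with stage
parameters, seeds and the package version; reruns with the same seeds
produce digest-identical artifacts. The `neoncts` CLI exposes the stages
individually (`simulate`, `window`, `extract`, `cluster`, `fit`,
`evaluate`) and as `run-all`.

The test suite exercises the pipeline at a deliberately desk-scale size
chosen to keep a full run on one CPU in tens of seconds: 200-patient
cohorts (~4,000 patient-days, ~8,000 featurized windows, ~230 viable
operations), ten replicate seeds for the signal-recovery check, and
smaller 60-patient cohorts with a 30% death fraction for the null
calibration — under the null all patients are exchangeable, so raising the
event count only improves the precision of the AUC ≈ 0.5 check at fixed
compute. Published-scale numbers that depend on the real cohort (AUCs
around 0.8, 81% variance explained) are qualitative references, not
reproduction targets; the package's own recoverable quantities are the
analytic nulls, worked identities, and oracle equivalences that the
acceptance suite computes.

## Known limitations

- The generator's functional forms are chosen for phenotype fidelity, not
  physiology; absolute effect sizes of the planted signatures are
  arbitrary in real-data terms.
- The catalog is a representative grid (120 operations/signal), not an
  enumeration of thousands of published operations; family coverage, not
  census fidelity, is the goal.
- Backward selection on 20 candidates with ~50 positive patient-days can
  overfit in-sample; only the cross-validated numbers should be read.
- MI distances on ~4,000 records carry finite-sample bias (independent
  columns land near 0.97, not 1.0); this does not affect the ranking used
  by k-medoids.
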