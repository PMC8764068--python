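# neoncts

Highly comparative time-series analysis of neonatal vital signs for
short-term mortality risk.

Continuous bedside monitoring in a neonatal intensive care unit produces
0.5 Hz heart-rate (HR) and oxygen-saturation (SpO2) streams that carry
early signatures of deterioration — reduced heart-rate variability, fewer
small accelerations, transient decelerations, drifting oxygen saturation.
Rather than hand-picking one statistic, this package screens a catalog of
time-series *operations* (an algorithm plus parameters plus a named
output) over 10-minute windows, reduces the redundant results to a small
representative set, and fits constrained logistic models of death within
the next 7 days:

1. **Windowing** — vitals are grouped into non-overlapping 10-minute
   windows of exactly 300 samples; one window per patient-day is kept
   (random, seeded) or the day is averaged.
2. **Feature extraction** — 120 operations per signal across eleven
   families (distribution, correlation, stationarity, symbolic
   transforms, entropy, trend, spectral HRV bands, time-series model
   fits, wavelets, nonlinear embedding, extreme values), including
   successive increases, a moving-threshold extreme-event model,
   surprise, a coupled random-walk fit, and the classic sample-entropy
   grid SampEn(m, r·SD) for m ∈ {1,2,3}, r ∈ {0.10, 0.15, 0.20, 0.25}.
3. **Reduction** — results are winsorized, squashed with an
   outlier-robust sigmoid f(v) = 1/(1+exp(−(v−median)/(IQR/1.349))),
   discretized into ten equiprobable bins, and clustered by k-medoids
   (k = 20) under the normalized mutual-information distance
   d = 1 − MI/√(H_a H_b); each cluster contributes one representative
   (best univariate AUC, or the medoid).
4. **Modeling** — the representatives enter a logistic regression;
   backward elimination on Wald p-values keeps at most five features.
   Performance is the pooled held-out AUC under patient-grouped,
   outcome-stratified tenfold cross-validation, broken down by
   days-until-death horizon, plus sensitivity = PPV and lift at a
   flag-count threshold equal to the event rate.

Everything runs end to end on a synthetic NICU cohort generator whose
pre-mortem effect sizes are explicit knobs, so the whole pipeline is
testable without any patient data: planted effects must be recovered, and
a null cohort (effects off) must score at chance. The audience is
researchers prototyping vital-signs risk analytics and anyone who needs a
tested, seedable reference implementation of these operators.

## Worked example

```bash
neoncts init-config --out demo.yaml   # edit cohort/pipeline settings as needed
neoncts run-all --config demo.yaml --seed 1 --out run/
```

or in Python:

```python
from neoncts.pipeline import default_config, run_pipeline

cfg = default_config(n_patients=40, death_fraction=0.15, seed=1,
                     stay_days_mean=12, stay_days_min=5, stay_days_max=20)
result = run_pipeline(cfg, out_dir="run")
print(round(result.report.cv_auc, 3))
print(result.selected_ids)
print({d: round(a, 2) for d, a in result.report.horizon_aucs.items()})
print({k: round(v, 3) for k, v in result.report.threshold_metrics.items()})
```

which prints (machine-exact under the same seeds):

```
0.994
['HR:sample_entropy(m=3,r_frac=0.1)->sampen', 'HR:trend()->intercept',
 'HR:distribution()->iqr', 'SPO2:trend()->intercept',
 'SPO2:moving_threshold(decay_b=0.1,rate_a=0.5)->mean_gap']
{1: 0.98, 2: 0.98, 3: 0.96, 4: 0.98, 5: 0.99, 6: 1.0, 7: 0.99}
{'threshold': -5.719, 'sensitivity': 0.905, 'ppv': 0.905, 'lift': 10.125}
```

Reading the output: the cross-validated AUC of 0.994 says held-out
patient-days of dying patients rank above survivor days almost always —
expected, because this demo cohort plants strong pre-mortem effects
(variability halved, SpO2 drifting −2%/day). The five selected features
mix HR regularity (sample entropy, IQR) with SpO2 level/extreme-event
measures, mirroring the two planted signatures. Horizon AUCs stay high
from 7 days out because the SpO2 drift spans the whole final week. At a
flagging threshold equal to the event rate (~8.9% in this small demo),
sensitivity and PPV coincide at 90.5%, a lift of 10.1 over prevalence.

The run directory contains the cohort files, the serialized catalog,
cluster solution, fitted model, per-sample predictions, the evaluation
report, and `manifest.json` — a provenance record with stage parameters,
seeds and SHA-256 digests of every artifact (reruns with the same seeds
reproduce identical digests).

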