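# seasonalcgm

Seasonal stochastic local modeling for glucose forecasting from continuous
glucose monitoring (CGM) data under variable-length, time-stamped daily
events.

## The problem

CGM traces in type 1 diabetes are not periodic: meals, nights and
hypoglycemia treatments start at different times and last different spans
every day, so classical seasonal time-series models do not apply directly.
Yet the glucose response *within* one kind of event is highly structured.
This package makes that structure usable by practitioners building glucose
predictors that need nothing beyond CGM and event timestamps (no carb
counts, no insulin records):

1. **Partitioning** — the trace is cut into event-to-event subseries,
   grouped into meals (M), night (N) and hypoglycemia treatment (H), and
   blank-padded to a common length `L` per group.
2. **Clustering** — subseries are clustered by fuzzy c-means with the
   partial-distance strategy, `d(a,b) = sqrt(L/(L−B) Σ Dᵢ²)` (blanks
   contribute nothing), with the Fukuyama–Sugeno index selecting the number
   of clusters.
3. **Local models** — each cluster's subseries, preceded by `Pr = 5`
   pre-samples, are concatenated into a series with enforced seasonality
   `s = L + Pr` and fitted with a SARIMA (p,d,q)(P,D,Q)s model whose
   likelihood ignores blanks and pre-samples (state-space missing-data
   filtering).
4. **Real-time integration** — at each sample the local forecasts are
   combined, `Ĝ(t|tp) = Σ γᵢ(tp) Ĝᵢ(t|tp)`, with two-step fuzzy weights
   (onset-segment screening at 20% of the maximum membership, then a 20-min
   sliding-window refinement). A crispness index CI reports how single-model
   the prediction is; a normality index NI (mean possibilistic membership)
   flags CGM behavior unseen in training.

A synthetic scenario generator (meals with realistic timing/size
variability, carb-counting error, circadian insulin sensitivity, the 15-15
hypoglycemia rescue rule, optional missed boluses and exercise) provides the
standard training / "normal" / "abnormal" datasets; see `docs/methods.md`.

## Worked example

```python
from seasonalcgm import SeasonalGlucoseModel, build_datasets

data = build_datasets(days_train=14, days_val=7, seeds=(11, 12, 13))
train = data["train"]

model = SeasonalGlucoseModel(train.cgm, train.events,
                             c_range=range(2, 5),
                             exclude_events=train.exclusion_flags)
results = model.fit(seed=0)
print(results.summary())
```

```
Seasonal stochastic local glucose model
======================================================
Partition M: n=41 subseries, L=90, s=95, c=4, eta=0.0231
  cluster 1: 16 subseries, SARIMA(2,0,0)(1,0,0)95  AICc=4039.2
  cluster 2: 8 subseries, SARIMA(2,0,0)(1,0,0)95  AICc=2089.4
  cluster 3: 11 subseries, SARIMA(1,0,0)(1,0,0)95  AICc=2632.9
  cluster 4: 6 subseries, SARIMA(2,0,0)(1,0,0)95  AICc=1512.9
Partition N: n=13 subseries, L=59, s=64, c=4, eta=0.09
  ...
Untrained partitions (no usable data): H
```

Fourteen days of training give 41 meal subseries (missed-bolus postprandial
periods excluded) regularized to L = 90 samples, hence seasonality 95; the
Fukuyama–Sugeno scan picks 4 meal clusters, each with its own seasonal AR
model. No hypoglycemia occurred in this quiet scenario, so the H partition
is left untrained and flagged.

```python
val = data["val_normal"]
report, replayed = results.validate(val.cgm, val.events, ph_minutes=[30])
print(report[report.partition == "overall"]
      [["PH_min", "n_predictions", "RMSElast_mean", "MAPElast_mean"]])
```

```
   PH_min  n_predictions  RMSElast_mean  MAPElast_mean
2      30           1801           4.52           2.73
```

Replaying the independent 7-day "normal" set gives a 30-min-ahead RMSE of
4.5 mg/dL (MAPE 2.7%) over 1801 predictions — versus 5.8 mg/dL for a
zero-order-hold baseline on the same residuals. On the "abnormal" set
(weekly missed boluses, Tue/Thu/Sat exercise), samples with NI below 0.2
carry a median absolute 60-min residual about 1 mg/dL larger than the rest
(Wilcoxon rank-sum p ≈ 1e-7), i.e. the normality index localizes the
planted unrepresented behavior.

There is also a CLI over the same pipeline:

```bash
seasonalcgm simulate --out data --days-train 14 --days-val 7 --seed 11
seasonalcgm train    --data data/train --out bundle --seed 0
seasonalcgm predict  --bundle bundle --data data/val_normal --out stream.csv --ph 30
seasonalcgm evaluate --bundle bundle --data data/val_abnormal --out eval
```

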