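# Methods

`seasonalcgm` forecasts continuous glucose monitoring (CGM) traces in type 1
diabetes by turning a fundamentally non-periodic signal into a seasonal one.
Daily life is punctuated by time-stamped events — meals, the night period,
hypoglycemia treatments — and the glucose excursion following an event of a
given kind tends to resemble other excursions of that kind. The package
exploits this by modeling *event-to-event* segments rather than the raw
trace.

## Model

**Partitioning.** Given a CGM series `G(t)` (5-min sampling, mg/dL) and an
ordered event log, each event opens a subseries that runs to the next event
(the last one to the end of data). Subseries are grouped by the label of
their starting event into three partitions: meals `M` (Breakfast, Lunch,
Dinner pooled), night `N`, and hypoglycemia treatment `H`. Within a
partition, subseries are padded with trailing blanks (NaN) to the maximum
observed length `L`, so that corresponding samples across event instances
align.

**Clustering with missing data.** Padded subseries are clustered with fuzzy
c-means using the partial-distance strategy (PDSFCM): for vectors `a, b` of
length `L` with `B` positions blank in either,

    d(a, b) = sqrt( L/(L−B) · Σᵢ Dᵢ² ),   Dᵢ = 0 if aᵢ or bᵢ blank, else aᵢ−bᵢ,

which reduces to the Euclidean distance for complete data. The fuzzy
objective `J_m = Σᵢ Σⱼ u_{ij}^m d²(xⱼ, νᵢ)` is minimized by alternating
optimization. One deliberate choice: the prototype update weights each row
by `u^m · L/(L−B_j)` on its observed coordinates. The common
partial-distance update omits the `L/(L−B_j)` factor; including it makes the
update the exact minimizer of `J_m`, so the objective is provably
non-increasing at every iteration, and the two coincide whenever rows have
equal blank counts (in particular on complete data, where the algorithm is
ordinary FCM). Initialization draws memberships from a symmetric
Dirichlet(1) per column; 5 seeded restarts; convergence when the largest
membership change falls below 1e−5 (cap 200 iterations).

The number of clusters is chosen by the Fukuyama–Sugeno index
`FS = Σᵢⱼ u^m [d²(xⱼ,νᵢ) − ‖νᵢ − ν̄‖²]` (lower is better), scanned over
c = 2..10 by default, with `ν̄` the mean of the prototypes. Partitions with
fewer than 10 subseries skip clustering and use a single model whose
prototype is the blank-aware elementwise mean.

**Seasonal local models.** The subseries crisp-assigned to a cluster are
concatenated in event order, each block preceded by `Pr = 5` pre-samples
(the CGM immediately before the event, feeding the autoregressive terms at
onset). The concatenation has enforced seasonality `s = L + Pr` and is
modeled as SARIMA (p,d,q)(P,D,Q)_s, fitted by maximum likelihood in a
state-space representation (statsmodels' SARIMAX Kalman filter). Samples
that are blanks or pre-samples enter the filter as missing observations:
they trigger the prediction step only and contribute no innovation to the
likelihood — residuals at those positions are effectively weighted zero.
Orders are selected by a small-sample-corrected information criterion
(AICc) computed over scored samples only, with ties broken toward fewer
parameters then lexicographically smallest order. The intercept is estimated
unless the model is differenced; d and D are capped at 1.

Two estimation profiles exist. Order search uses a speed profile:
concentrated innovation variance, masked-OLS starting values for the
(seasonal) AR coefficients, finite-difference gradients and a loose L-BFGS
stopping rule, no covariance matrix. Fits whose standard errors matter
(`compute_cov=True`) use the exact complex-step score and tight tolerances.
Point forecasts are identical under concentration, so the speed profile is
safe for prediction.

**Real-time integration.** At prediction time `tp` inside an event started
at `tek`, each local model produces a forecast `Ĝᵢ(t|tp)` conditioned on its
cluster history plus the current partial block. The integrated forecast is
`Ĝ(t|tp) = Σ γᵢ(tp) Ĝᵢ(t|tp)` with weights computed in two steps:

1. fuzzy membership of the onset segment `[tek, tp]` against the prototype
   slices discards clusters below `mu_factor = 0.2` of the maximum
   membership (survivor set `I2`);
2. membership of a short window `[tp − W, tp]` (W = 4 intervals = 20 min,
   endpoint inclusive, truncated at the onset) renormalized over `I2` gives
   γ.

Prototype slices beyond `L` hold their last value constant. When an event
closes, the finished subseries (tail-padded or truncated to `L`) and its
pre-samples are appended to the seasonal history of the cluster with the
highest full-segment membership; model coefficients are not re-estimated
online.

**Diagnostics.** Two per-sample indices accompany each forecast:

* crispness `CI = [2(1−1/c)]⁻¹ Σ|γᵢ − 1/c|` ∈ [0,1] — 1 when a single local
  model dominates, 0 when all contribute equally (defined as 1 for c = 1);
* normality `NI = |I2|⁻¹ Σ γᵢᴾ` with possibilistic memberships
  `γᵢᴾ = [1 + (η d²)^{1/(m−1)}]⁻¹` on the same window — low NI means the
  recent CGM shape is far from *every* prototype, i.e. the predictor is
  extrapolating. Behavior below `NIthr = 0.2` is flagged abnormal.

The possibilistic scale η is "a constant" in the model definition; here it
is calibrated per partition as the reciprocal of the median squared
window-distance between training rows and their own prototypes, so that a
typical training window scores `γᴾ = 0.5` at m = 2 (ceiling 1e6 if training
distances degenerate). η scales inversely with squared glucose deviations.

**Validation metrics.** Two residual conventions: `RMSEtraj`/`MAPEtraj`
score each full predicted trajectory (one value per prediction, averaged
over predictions); `RMSElast`/`MAPElast` score the PH-ahead point
predictions (one value per subseries from its `lᵢ − PH` residuals, averaged
over subseries; subseries with `lᵢ ≤ PH` are discarded). Trajectory origins
run over `tp ∈ [teᵢ, teᵢ₊₁ − PH]`. Reports pool per-item values and give
mean, SD, median and quartiles, per partition and overall. The NI analysis
groups PH-ahead absolute residuals by `NI(tp) <` vs `≥` a threshold
(0.1..0.9) and reports group medians, their difference and a two-sided
Wilcoxon rank-sum p-value.

## Synthetic scenario

The simulator emulates the event and variability structure of an open-loop
therapy scenario; it is an impulse-response stand-in, not a physiological
model. Per day: three meals, nominal 40/90/60 g at 7:00/14:00/21:00,
mealtime SD 20 min, size CV 10%; boluses cover the *announced* carbs
(actual × (1 + U(−30%, +10%)) — patients under-count on average) at a fixed
carb ratio; the night event starts 6 h after dinner. Glucose is

    G(t) = G_b + Σ_meals grams·f·g_m·r(t−t_m; τ_m)
               − S(t) Σ_boluses units·g_i·r(t−t_b; τ_i)
               + exercise effect + AR(1) noise,

with response kernel `r(t; τ) = (t/τ)·e^{−t/τ}` (peak `e⁻¹` at `t = τ`, so
a 90 g meal at gain 3 produces a ≈ 99 mg/dL excursion — this normalization
was chosen precisely so that meals and matched boluses roughly cancel and a
missed bolus produces sustained hyperglycemia of realistic size).
Per-event jitter: time constants ±30%, bioavailability `f` ±10%. Circadian
insulin sensitivity `S(t) = 1 + 0.3·sin(2πt/24 h)` (peak 6:00). The 15-15
rule treats readings below 70 mg/dL with 15 g fast carbs (τ = 15 min),
rechecking every 15 min; each episode logs a single HypoTreatment event at
its first rescue. Output is clamped to the CGM range [40, 400] mg/dL.
Default patient: basal 120 mg/dL, carb ratio 10 g/U, meal gain
3 (mg/dL)/g, insulin gain 30 (mg/dL)/U, τ_meal 40 min, τ_ins 55 min, AR(1)
noise with stationary SD 2 mg/dL and coefficient 0.7.

Exercise (abnormal scenario): Tue/Thu/Sat, nominal 60 min at 18:00 (start
SD 20 min, duration CV 10%); insulin sensitivity ×1.5 during the session
and a 3 h tail; a −0.5 mg/dL/min drop accumulates during the session and
decays exponentially (τ = 90 min) across the tail — a never-recovered shift
would be unphysical, and the model statement leaves the post-session fate
of the drift open. Missed boluses: `sporadic` mode (training) spaces them
at least 14 days apart (~1 per 20 days); `weekly` mode (abnormal
validation) plants one per week. Training postprandial periods following a
missed bolus are flagged for exclusion.

The three standard datasets are: training 120 days (sporadic missed
boluses, excluded), "normal" validation 60 days (same generative law),
"abnormal" validation 60 days (weekly missed boluses + exercise). A
four-month schedule yields 360 meal and 119 night events (the last night
starts past the horizon end at midnight after the final day).

What the simulator does *not* reproduce: gastric-emptying nonlinearity,
insulin-on-board dynamics, sensor drift/dropout, meal announcements
decoupled from consumption timing, inter-patient parameter distributions.
Passing tests therefore demonstrate that the framework recovers structure
it is designed for under realistic event statistics — not clinical accuracy
on real CGM data.

## Problem sizes and numerical choices

* The default end-to-end ("desk"/smoke) run trains on 14 days and validates
  on 7-day sets; the scenario generator itself defaults to the full
  120/60/60-day design. Smoke-scale cluster counts are scanned over 2..4.
* The pipeline's default SARIMA candidate list is compact —
  (1,0,0)(1,0,0)s, (2,0,0)(1,0,0)s, (1,0,1)(1,0,0)s, (1,0,0)(0,0,0)s — the
  exhaustive p ≤ 4, q ≤ 4, P ≤ 2, Q ≤ 2, d,D ≤ 1 grid is available but is a
  compute-cluster workload at s ≈ 100.
* Replay forecasting uses one Kalman-filter pass per (cluster, subseries):
  filtered states at every origin are propagated through the transition
  matrix to get all fixed-origin h-step forecasts at once (exactly equal to
  refiltering per origin). Conditioning history is capped at the 12 most
  recent seasonal blocks; seasonal lags reach back at most a couple of
  blocks, so older data carries no forecast information.
* Degenerate cases: zero partial distance yields a one-hot membership
  (first zero-distance cluster); subseries shorter than 2 samples are
  dropped with a warning; clusters with fewer than 5 subseries skip the
  80/20 split and fall back to a minimal candidate chain
  ((1,0,0)(0,0,0) then intercept-only); empty prototype coordinates during
  clustering fall back to the observed column mean; ties in crisp
  assignment go to the lowest cluster index.
* An event group absent from training (commonly `H`: no hypoglycemia under
  quiet settings) leaves that partition untrained; strict prediction raises
  on its events, offline validation skips them.

## Known limitations

* The two-step weights are recomputed from scratch each sample; no
  smoothing across samples, so γ can switch abruptly near cluster
  boundaries (visible as CI dips).
* Clustering with very few subseries per cluster (night partition on short
  training horizons) can select more clusters than the data support; the
  FS index is scanned, not penalized for cluster count.
* η calibration uses the training windows only; a distribution shift in
  sensor noise rescales NI.
* Online updating is limited to history appending — prototypes and SARIMA
  coefficients are frozen after training.
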