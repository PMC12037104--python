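# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
design decisions taken where more than one reasonable reading existed.

## Harmonization

Input abundance tables are keyed by KEGG compound IDs (`C#####`). Free-text
metabolite names are renamed through a user-supplied mapping table; a
mapping that sends two input features to the same compound ID raises rather
than merging, because abundances from distinct assays are not commensurable.
Cross-study comparison restricts all matrices to the shared feature set in
lexicographic order (bit-stable outputs).

Missing abundances are filled with **half the per-metabolite minimum**
observed value — the standard treatment for left-censored (below detection
limit) missingness in quantified metabolomics. The per-feature (not global)
minimum is used, since detection limits are compound-specific. The operation
is idempotent and never touches observed entries.

**Outliers** are measurements farther than two sample standard deviations
(n−1 denominator) from their condition-group mean, computed per compound and
per condition; the condition defaults to the target class. The strict
inequality means a constant feature flags nothing. Flagging returns a mask;
the default policy blanks flagged cells and re-imputes once (a single pass,
deliberately — iterating to a fixed point would progressively erode genuine
distribution tails), preserving the matrix shape for downstream models.
After an upper outlier is blanked, half-minimum refill places a low value
there; this is a known conservative bias of the policy and the report of
flagged cells allows a caller to apply a different one.

Splits are stratified by the target label (default 80/20, seed 42). The
split is assigned once and shared by every downstream stage so that
before/after comparisons are paired.

## Scaling

Eight per-feature transforms plus `none`, in the canonical forms used across
metabolomics pretreatment: centering `x−x̄`, autoscaling `(x−x̄)/s`, pareto
`(x−x̄)/√s`, range `(x−x̄)/(max−min)`, vast `((x−x̄)/s)·(x̄/s)`, level
`(x−x̄)/x̄`, `log10 x`, and power `x^q` with `q = 1/2` by default.
Parameters (mean, sd with n−1, min, max) are estimated **on the training
split only** and applied unchanged to held-out data; a fit-on-all mode
exists for exploratory reproduction but is not leakage-free. Degenerate
denominators (constant feature, zero mean for level/vast) fall back to plain
centering with a warning instead of emitting NaN columns. `log10` of a
non-positive value is a hard error unless the epsilon-offset mode is
explicitly enabled. All transforms are monotone within a feature, and the
affine ones (plus log10/power on their domains) are exactly invertible from
the stored parameters.

## Classifiers

Five families at contract level: k-nearest neighbours, ridge classifier,
support-vector regression thresholded at 0.5 on 0/1-encoded labels
(equivalently the sign of `prediction − 0.5`), random forest, and a
feed-forward network (ReLU hidden layers, sigmoid-activated output through
scikit-learn's `MLPClassifier`, adam optimizer). Hyperparameters are chosen
by stratified k-fold (default 10) cross-validated accuracy over small pinned
grids — k ∈ {3,5,7}, ridge α ∈ {0.1,1,10}, 200 trees, hidden (32,16) with
200 epochs at learning rate 1e−3 — all config-overridable. Classes are not
re-weighted. kNN/ridge/random-forest retraining is bit-stable under a fixed
seed; the network is floating-point stable to |Δaccuracy| < 0.02.

## Drift detection

DDM and EDDM are implemented from their original published update rules as
streaming state machines (see the `metadrift.drift` docstring for the
formulas). Numeric defaults — 30 minimum instances/errors, 2σ/3σ warning
and drift thresholds, α = 0.95, β = 0.90 — are the values of the original
publications; all are configuration keys. Comparisons are strict (`>`, `<`):
a statistic exactly at its threshold does not fire, so an all-zero or
perfectly regular stream produces no events. Every drift is preceded by, or
coincides with, a warning in its episode; a drift resets all detector state.
Detectors run post hoc over the error stream of a fixed, already-trained
model; no online updating takes place. Both detectors are verified, event
list for event list, against an independent from-scratch recomputation on a
thousand random streams; EDDM's running variance is kept as exact sums so
that boundary ties (reachable because error distances are integers) resolve
identically in any correct recomputation.

Two properties of DDM at its published defaults matter for interpretation:

* **Degenerate baseline.** If no error has been seen since the last reset,
  `p_min = s_min = 0` and the "3σ" condition degenerates to *any error at
  all* — the binomial approximation is meaningless at p = 0. Such events
  are still emitted (they are the detector's defined behaviour) but are
  flagged, and the pipeline's reporting and nomination layers exclude them
  (`confirmed_events`).
* **Warm-up false alarms.** On a stationary stream the historical minimum is
  often locked in the small-n warm-up region (for an error rate of 0.1,
  P(≤2 errors in the first 30 instances) ≈ 0.41), giving a hair-trigger
  threshold that the true rate later crosses. Measured on stationary
  Bernoulli(0.1) streams of length 1000, ~40% contain at least one drift.
  This is a property of the published rule itself — an independent
  recomputation agrees event-for-event — and is documented rather than
  patched; the confirmed-event filter removes only the p_min = 0 subset.

## Error streams and the prequential analog

Section B builds binary misclassification streams ordered ascending by a
candidate covariate (stable tie-break on sample ID). The default stream is
**out-of-fold**: 10-fold stratified cross-validated predictions over the full
cohort using the hyperparameters selected in Section A — the batch analog of
prequential evaluation, giving every sample an honest error indicator. The
stream is replicated over several cross-validation shuffles (default 8);
reported event counts are per-replicate medians of confirmed events, which
de-noises the counting without touching the detector. Fixed-model streams
over the test split or the whole cohort are available by configuration.

## Confounder nomination and the threshold

The association between events and a covariate is defined as the covariate
value of the ordered sample at each event index; candidate covariates are
scanned one at a time and ranked by how tightly their warning values cluster
(smaller range = stronger candidate), with the number of replicate streams
containing a confirmed drift as the primary vote. `derive_threshold`
implements three rules on the association: mean of warning values, mean of
drift values, and the midpoint of the pooled range.

The pipeline's default threshold estimate goes one step further. Raw event
indices carry detection latency (a drift is confirmed tens of samples after
the change) and warning entries lock onto early noise minima, which costs
several years of bias and variance on age-ordered cohorts. The pipeline
therefore separates *whether* from *where*: DDM must confirm a drift in a
replicate stream, and the onset is then estimated on that stream by the
classical maximum-likelihood two-segment split (every prefix/suffix split
scored under independent Bernoulli rates, restricted to rate increases).
The reported threshold is the median refined onset over replicates. On the
default simulated conditions this recovers the true threshold with a bias
below half a year, versus 2–4 years of spread for the raw event-value rules,
which remain available (`confounder.threshold_rule`) and are exercised by
tests.

Covariates can be clinical (age, BMI) or any metabolite column copied into
the clinical table (e.g. creatinine), and an association plot with event
markers and an optional grey-scale concentration track can be written per
covariate. Whether a nominated covariate is biologically plausible is the
expert step: interactive confirmation by default, `--auto-accept` to take
the top-ranked nomination.

## Correction

Boundary samples (value equal to the threshold) go to the lower stratum — a
convention that had to be fixed and is tested.

**Segmentation** trains one model per stratum; each stratum keeps its own
train/test assignment. It is the correct fix when the concept genuinely
differs across the threshold (e.g. effect reversals), because each model
sees an internally consistent relationship; its cost is that each model
trains on a fraction of the cohort, so it needs cohorts that can afford the
split (strata with fewer than two samples per class are rejected with advice
to use stratified scaling).

**Stratified scaling** fits the scaling parameters separately within each
stratum on training samples and applies them stratum-wise; no sample is
lost and sample order is preserved. With the threshold at infinity it
reduces exactly to ordinary scaling. Because every scaling transform is
per-feature monotone, per-stratum parameters alone can only correct
distributional (mean/variance) shifts across the threshold — they cannot
repair a reversed feature→label relationship, whose strata have identical
marginals. The two-column pairing of each metabolite with the binarized
confounder is therefore realized in full: the stratum indicator is appended
as a model input (`add_indicator`, on by default), which lets
interaction-capable models condition on the stratum. Linear models cannot
represent the required interaction and greedy trees rarely find it (the
indicator has no marginal signal), so for reversal-type drift the pipeline
defaults to segmentation.

After correction the same detector configuration is re-run on the corrected
models' streams with the same ordering and replicate seeds, making
before/after accuracies and confirmed-event counts a paired comparison.

## The simulator

`generate_cohort` emulates a two-class metabolomic cohort with a hidden
age-threshold concept change. Defaults, chosen once from the cohort
structure the workflow targets and then frozen:

* **n = 500 samples, 22 metabolites** with baseline abundances uniform in
  8–12 arbitrary units and unit within-class Gaussian noise, features
  independent;
* **sex effect 1.0** — a between-class mean shift of one within-class sd per
  metabolite (each class shifted ±0.5 sd), alternating direction across
  metabolites; strongly sex-dimorphic metabolites such as creatinine show
  effects of this order, and it puts baseline cross-validated accuracy in
  the 0.8–0.9 range typical of published sex classifiers on small panels;
* **age** drawn as 18 + Exponential(scale 5.77) years clipped to [18, 75]
  (median ≈ 22, ~75% of samples below 26), emulating the young-adult-heavy
  age structure of student-recruited healthy-volunteer cohorts; a uniform
  option exists;
* **true threshold 26 years**; beyond it, on a random half of the
  metabolites, the feature→label relationship changes per `drift_mode`:
  `flip` interpolates the effect from unchanged (magnitude 0) to fully
  sign-reversed (magnitude 1, the default), `attenuate` shrinks it, and
  `shift` adds a class-independent offset (a covariate-shift rather than
  concept-drift mechanism, which per-stratum scaling does fix);
* **missingness 2%, left-censored** — the lowest measurements of each
  metabolite fall below a detection limit, which is the missingness
  mechanism half-minimum imputation is designed for (missing-completely-at-
  random injection would make the imputed value a gross outlier instead);
* **outliers** at rate 0.005, ±5 noise-sd spikes.

Everything derives from one seed; infeasible draws (an all-missing column)
are regenerated with a reported retry, up to ten times.

What the simulator does *not* emulate: between-metabolite correlation,
instrument batch effects, longitudinal repeated measures, non-Gaussian
(log-normal, heavy-tailed) abundance distributions, and multi-site cohort
heterogeneity. Passing recovery tests on simulated cohorts demonstrates that
the detection→nomination→correction loop works when its assumptions hold;
it does not certify performance on real cohorts, where the confounding
signal is weaker and entangled with correlated features.

## Recovery study, measured behaviour and known limitations

The acceptance study runs 50 independent default cohorts through the full
pipeline (kNN family, autoscaling). Measured at these conditions: the
derived threshold clusters at 26.0–26.4 with ~0.6 y spread (≈90% of
replicates within ±2 y of the true 26); mean out-of-fold accuracy rises by
≈0.07 after segmentation at the derived threshold; the median confirmed
drift count falls to zero and the modal replicate is drift-free.

Limitations worth knowing:

* After segmentation the high-age stratum trains on ~¼ of the cohort, so
  its error rate stays somewhat above the young stratum's; DDM honestly
  reports that residual sample-size-driven step in roughly half the
  replicate streams, which is why the after-correction drift count is
  "modal zero" rather than "always zero".
* DDM's warm-up false alarms (above) mean raw event counts on low-error
  streams should not be read as evidence of drift; use the confirmed
  counts.
* EDDM needs ≥ `min_errors` inter-error distances since its last reset
  before it can signal at all, so on short, accurate streams (a few dozen
  errors) it is typically silent; it is reported alongside DDM but the
  nomination layer keys on DDM.
* One covariate is corrected per pass; joint multi-covariate correction is
  out of scope.
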