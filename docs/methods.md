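# Methods

## Model and procedure

`cogrisk` operationalises cognitive risk as the joint requirement of a
favourable cognitive state and adequate task performance, per task, then
aggregates across a battery.

**Feature extraction.**  For each participant × task:

* *Pupil dilation (%)*: the eye tracker samples pupil diameter nominally
  every 17 ms.  The baseline is the closed–open window [0 s, 1 s) of task
  time; the feature is `100·(mean_rest − mean_base)/mean_base`.  Missing
  samples are excluded from both means — they are blink evidence, not
  diameters.
* *Blink rate (1/s)*: maximal contiguous runs of missing samples are
  counted as blink events (default), divided by task duration.  A raw
  missing-*line* count is also provided; at a 17 ms cadence a single
  ~136 ms blink spans ~8 lines, so the line convention runs roughly 8×
  higher and is not used downstream.  The two conventions satisfy
  `events ≤ lines`, with equality iff every run has length 1.
* *Normalized GSR*: per-second conductance divided by the participant's
  pooled mean conductance over all their tasks, averaged over the task
  (`per_second_mean`).  A second convention divides by the task length
  once more (`per_second_mean_over_duration`); at ~250 s task lengths it
  yields magnitudes near 0.004, matching the scale on which the
  calibration centres are expressed, and is therefore the generator's
  default, while the standalone extractor defaults to the literal
  single-division reading.  Which division the original protocol used is
  not decidable from its description; both are first-class and the
  pipeline threads one convention through consistently.

**Clustering.**  Per task, features are standardized (mean 0, sd 1) —
pupil percentages are ~3 orders of magnitude larger than normalized GSR,
so unscaled K-means would cluster on pupil alone; scaling can be turned
off for sensitivity checks.  K-means uses k-means++ seeding, Lloyd
iterations, best of 10 restarts by inertia, empty clusters repaired by
splitting off the farthest point; deterministic given a seed.  Candidate
counts {2, 3, 4} are scored by mean silhouette (Euclidean, on the scaled
features; singleton and zero-distance points contribute 0) and ties break
toward the smaller k.  Centres are reported in original units; for stable
output the cluster with the higher pupil-dilation centre is listed first.
Silhouettes are also displayed on a 0–100% scale via `50·(s+1)`.

**Risk rule.**  Tag 0 (risky state) goes to the cluster whose centre
matches the task's hazardous state: higher pupil dilation for
cognitively loading tasks (both P300 levels, feedback motor imagery),
lower for monotony-dominated tasks (both SSVEP levels, plain motor
imagery).  Pupil dilation is the primary indicator; an exact pupil tie
falls back to the GSR centre in the task's expected direction, then
blink rate; a full three-way tie raises an error rather than guessing.
Expected blink directions are stored per task, not per paradigm, because
the two P300 difficulty levels carry opposite expected blink effects.
Task risk is *low* iff tag = 1 and performance ≥ 70%; general risk is
*low* iff ≥ 3 of 6 task risks are low.  Both thresholds are parameters
with locked defaults.  The performance buckets are <70 bad, 70–90 good
(both ends inclusive), >90 excellent; only the 70 boundary, which is
explicitly "at least", enters the risk rule.

**Consistency suite.**  The rule-based general-risk label is a
deterministic function of 24 per-participant inputs.  Logistic
regression (IRLS with a 1e-8 ridge on the normal equations; all 24
predictors entered as one block) will typically *separate* such labels:
iteration then stops at the cap with a separation flag, leaving a model
that classifies the training set perfectly — deliberately mirroring how
classical packages report a perfect classification table with
Nagelkerke R² = 1 rather than switching to a penalised (e.g. Firth)
fit, which would change the reported table.  The positive class for the
probability cut-off is *low risk* (the minority class); cut-offs 0.50
and 0.70 are both reported.  CART uses greedy Gini splits with
deterministic tie-breaks (lowest feature index, then lowest threshold);
zero-decrease splits of impure nodes are allowed by default so that
parity-like patterns resolve one level deeper, and with `min_leaf=1` and
unlimited depth the tree memorizes any consistent labelling.  The
network has one tanh hidden layer (default: half the input width,
rounded up) and a 2-unit softmax output, trained by cross-entropy
gradient descent for 2000 epochs at step 0.5 (batch) or 0.1 per block
(online/mini-batch, block size 8), deterministic given the seed.
Predictors are standardized column-wise before all three fits (affine,
so the logistic/CART fits are equivalent; it conditions the network).
Closed-form companions: paired-t rows from (mean, sd, n) with 95% CI
`mean ± t₀.₉₇₅,ₙ₋₁·sd/√n`; Nagelkerke
R² `(1−exp(2(LL₀−LL)/n))/(1−exp(2·LL₀/n))`; omnibus χ² `−2(LL₀−LL)`
on df = number of predictors; 2×2-table percents (per-class recall,
predicted-class marginals, overall).

## Synthetic cohorts: what they emulate, and what not

The generator emulates a 70-participant cohort over the six-task battery.
Each cell draws a latent state (risky with probability `mixture_weight`,
default 0.5 — real cluster sizes were not reported) and a feature triple
from a truncated normal around that state's published centre, truncated
to the published per-feature min/max box; task performance is truncated
normal with the published per-task moments, independent of the latent
state.  Cells are independent across tasks by default;
`participant_coupling` mixes in a shared participant-level draw, since
the ≥3-of-6 rule is sensitive to cross-task dependence.

**Per-state spread.**  Published tables give per-feature global spreads
and the two cluster centres but no within-cluster spread.  The default is
`cluster_sd_fraction = 0.15` of the global sd.  This value is calibrated
to two observable properties of the original analysis: the k = 2
silhouettes it produces (≈0.49–0.89, mean ≈0.61 across tasks) match the
published 0.59–0.78 range, and two-means clustering recovers the latent
states with median ARI 1.0 per task.  A fraction of 0.5 — the value that
best preserves the printed *pooled* spreads — produces silhouettes far
below the published ones and unrecoverable mixtures (median ARI ≈0.5–0.8),
so the pooled spread is the property knowingly sacrificed: generated
global sds run below the printed ones.

**Signal realisation.**  `invert_features_to_signals` builds a pupil
stream that is constant at `baseline_pupil_mm` (default 4.0 mm, a
typical adult diameter; not reported) for the first second and constant
at the dilated level after; blinks are `round(rate·duration)` runs of 8
missing samples (~136 ms; blink durations not reported) placed uniformly
at random, non-touching so the event count is preserved.  GSR is a
constant per-task level (no waveform detail was reported).  Task length
defaults to 250 s for the whole battery — individual task lengths are not
derivable from the protocol, and 250 s makes the duration-normalized GSR
magnitudes (~1/250) consistent with per-second conductance ratios near 1.
Rest-period carry-over in GSR is ignored.

**Identifiability of normalized GSR.**  Division by the participant's
overall mean makes the feature compositional: for any real recording the
duration-weighted mean of the per-second ratios is exactly 1, so a free
vector of six GSR targets is generally unrealisable.  `generate_cohort`
projects each participant's drawn targets onto this subspace (one
multiplicative factor per participant, typically ~0.85) and stores the
projected values — together with the quantised blink rates — as the
latent truth.  Extraction then reproduces the stored truth to floating
-point precision, while per-task GSR means sit slightly below the drawn
centres (inside the published min/max boxes).  Consequence for tests:
signal-level round trips are exact, but the *cohort-level* GSR
distribution is truth-after-projection, not the raw table values.

**What passing tests do not show.**  The generator draws independent,
truncated-normal, constant-within-task signals.  Real pupillometry has
luminance and gaze-angle artefacts, GSR has tonic drift and phasic
responses, blinks vary in duration, features correlate within
participants, and performance co-varies with state.  Tests passing on
these cohorts demonstrate the pipeline's correctness and the rule's
internal consistency, not field validity of the risk classes.

## Numerical choices and degenerate inputs

* Zero-sd draws (noise_scale 0) return the centre clipped to bounds.
* Standardization leaves constant columns at scale 1 with a warning.
* K-means: restart count 10, max 300 Lloyd iterations, convergence on
  unchanged assignments; permutation equivariance holds at the global
  optimum (tested on separated data).
* Silhouette: O(n²) pairwise distances; identical-point clusters and
  singletons contribute 0; k = 1 is an error.
* Logistic: IRLS capped at 100 iterations, ridge 1e-8, step tolerance
  1e-10; one-class outcomes are an error; separation is flagged when the
  uncapped fit classifies perfectly with near-zero deviance.
* MLP: non-finite loss raises immediately with a suggestion to reduce
  the step size; zero-init gives exactly (0.5, 0.5) outputs.
* Tagging and the risk rule validate their inputs (k = 2 only, tags in
  {0, 1}, exactly 6 task risks) and fail loudly with cell context.

## Known limitations

* The original cohort's 59/11 split and its classifiers' exact tables
  depend on unpublished raw data; the synthetic pipeline reproduces the
  *behaviour* (a ~4:1 split, perfect logistic/CART/batch-network
  consistency with separation) rather than those exact counts.
* CHAID and QUEST trees are not implemented; their published tables are
  consumed only as arithmetic inputs to the confusion-metrics routine.
* The network does not emulate any particular package's automatic
  architecture search, learning-rate schedule or stopping rule; only the
  architecture (tanh hidden layer, softmax output) and the three update
  granularities.
* Eye-tracker data loss other than blinks is not modelled; all missing
  runs count as blinks, as in the extraction rule.
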