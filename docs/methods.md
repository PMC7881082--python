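# Methods

This note records the scientific and numerical choices behind `seizurekit`:
what each stage computes, the conventions that pin the numbers down, what
the synthetic generator does and does not emulate, and where the design was
genuinely open.

## Epoching and labeling

Records are segmented into fixed-length epochs (default 10 s, i.e. 2560
samples at 256 Hz; both length and rate are configurable so desk tests can
use short, low-rate records). An epoch is *seizure* only when it lies
entirely inside an annotated interval and *normal* only when entirely
outside all of them; epochs straddling a boundary are discarded rather than
majority-labeled, which avoids introducing label noise with no principled
definition. Annotations are half-open second intervals `[start_s, end_s)`
in a sidecar CSV.

Two protocols cut epochs:

* **Continuous**: each annotated interval is tiled from its own start into
  consecutive non-overlapping epochs, trailing partial epochs dropped (a
  30-s event yields exactly 3, a 40-s event 4); the non-annotated remainder
  is tiled the same way. This models evaluating consecutive epochs of one
  patient.
* **Random**: a requested number of non-overlapping epochs per class is
  drawn uniformly at random under a seed. Uniformity among all
  non-overlapping placements is achieved with the order-statistics ("sorted
  uniform gaps") construction per eligible region, with slots allocated
  across regions by drawing without replacement from the pooled slot list.
  The capacity of a region of length L is ⌊L/w⌋; an impossible request
  raises an error stating the achievable count. Adjacent epochs are never
  allowed to overlap — an assumption, since overlap handling in random
  evaluation sets is often left unstated in the literature.

## Channel selection

Per epoch, channels are ranked by the population variance of their
amplitude, (1/K) Σ (x−μ)², and the top k = 3 are kept (ties broken toward
the lower channel index; asking for more channels than exist returns all
with a warning). The normalization differs from the 1/(N−1) used by the
feature-side variance; both are kept as stated conventions because a common
positive factor cannot change a ranking. Selection is recomputed per epoch
— the worked example applies it to a single epoch — rather than once per
record; per-epoch selection is the primary reading and lets the selection
track a moving focus. Scaling all channels by a common constant leaves the
selection invariant.

## Features

Eleven features per channel, then an element-wise arithmetic mean across
the selected channels. Conventions, each chosen to satisfy an exact,
testable identity or a worked example:

* **STD** uses 1/(N−1); **Var = STD²** (same normalization, so the
  invariant `var = std²` is exact).
* **SKW**/**KRT** use population moments: third and fourth standardized
  central moments; kurtosis is non-excess (Gaussian → 3, consistent with
  the 2.35–3.01 range of the worked example).
* **MOM** is the central population moment of order 4 by default (order is
  configurable). Order 4 is fixed by the identity MOM = KRT · σ_pop⁴, which
  the worked-example rows satisfy at printed precision.
* **POW** is Σ F·conj(F) over the *unnormalized* DFT, hence exactly
  N·Σx² (Parseval). Other DFT normalizations would change POW by N or N²;
  the convention is pinned so it cannot be silently substituted. Verified
  to 1e−9 relative (measured ~1e−15) against the time-domain sum.
* **ENT** is the Shannon entropy (natural log) of the epoch's amplitude
  histogram normalized to a probability vector, 100 bins by default; bins
  and log base are configurable. This is an assumption, not a reproduction:
  the histogram specification behind the worked example's printed entropies
  is unrecoverable (those values reach 4.84 > ln 100 ≈ 4.61, so they cannot
  come from a 100-bin natural-log histogram; no bin/base choice is
  recoverable from the printed numbers alone).
* Zero-variance signals: skewness and kurtosis are undefined and returned
  as 0 with a logged warning; "zero variance" is judged relative to the
  signal's own magnitude (spread ≤ 1e−12 of the RMS), since a constant
  signal plus float rounding is not meaningfully non-constant.
* Fewer than 4 samples is an error (fourth-moment features undefined).

Averaging is a plain element-wise mean; it commutes with input permutation
and is the identity on a single vector.

## Classifiers

Seven scikit-learn estimators behind one `train`/`predict` surface: SVM
(RBF, C = 1), bagged decision trees (100 learners), KNN (k = 5, odd to
avoid voting ties), LDA, logistic regression, CART decision tree (Gini,
unlimited depth), Gaussian naive Bayes. No hyperparameter set is canonical
for this pipeline, so the common toolkit defaults are used and every value
is overridable per call. All stochastic learners are seeded; the bagged
ensemble's base learner and size are likewise a choice, not a given.

Because the feature columns span ~10 orders of magnitude (SKW ~0.1 vs POW
~1e12), every model fits inside a pipeline that z-scores features with
training-set statistics; those statistics are frozen at fit time and
re-applied at prediction, never re-estimated. Seizure (`State == "s"`) is
the positive class everywhere.

## Validation and metrics

Confusion counts use seizure-positive conventions. The nine derived metrics
are all reported on the percent scale — including fall-out FP/(TN+FP) and
miss-rate FN/(TP+FN), whose definitions are sometimes written as bare
ratios but which are conventionally tabulated as percentages; the percent
scale is adopted uniformly. A zero denominator yields `nan` ("undefined")
with a warning, never 0. F1 is the harmonic mean of precision and recall
(percent in, percent out), so `sensitivity + miss_rate = 100` and
`specificity + fall_out = 100` hold identically.

Cross-validation is stratified K-fold (default K = 5), seeded and
reproducible; stratification keeps class balance in every fold (fold sizes
and per-class counts differ by ≤ 1). K equal to the row count degrades to
leave-one-out, where the stratification constraint is vacuous. Per-fold
confusions are summed into the pooled confusion before metrics are derived,
so every sample contributes exactly once.

### Abnormal-row filter

Visual removal of suspicious training points is operationalized as a
reproducible rule. Features are first compressed with `asinh` (linear near
zero, logarithmic at large amplitude) so the heavy-tailed amplitude
features cannot dominate; per column, a robust z-score is computed against
the row's own class (median center, 1.4826·MAD scale, MAD-zero columns
skipped), columns are oriented by the sign of the seizure-vs-normal median
difference, and the row score is the mean oriented z. Normal rows scoring
above the threshold (default 3) and seizure rows below its negative are
removed. The `asinh` compression and the own-class/oriented-mean scoring
are this package's choices; on clean synthetic tables the rule removes
nothing in ≥ 95% of seeded runs, while rows planted many robust SDs onto
the wrong side are always caught.

## Synthetic data

`simulate_record` emulates only the statistics the pipeline assumes:
23-channel, 256 Hz records of band-limited (1–30 Hz) 1/f-weighted colored
noise, per-channel SD 50 µV — colored rather than white so the entropy and
kurtosis features are non-degenerate and the spectrum is closer to scalp
EEG. During annotated intervals, designated burst channels (defaults: the
2nd, 6th and 21st of 23) additionally carry a rhythmic 3 Hz spike-wave
component (sinusoid plus a 25-ms Gaussian spike per cycle) whose RMS is
`amplitude_factor × background_sd`, making the expected ictal variance
(1 + factor²)× the interictal variance — 10× at the default factor 3. It is
*not* a physiological EEG model: no artifacts (EMG, eye-blink), no
spatial correlation between channels, no evolving seizure morphology, no
inter-patient variability. Passing tests therefore demonstrate that the
pipeline recovers a planted high-variance ictal signature, not clinical
performance; absolute accuracies on real recordings require the real
databases, which this package reads (EDF + annotation CSV) but does not
ship.

`simulate_feature_table` skips the signal stage for classifier tests: each
row draws a severity latent (class means ±effect/2, shared variance 0.25)
and each informative feature adds independent variance 0.75, so the class
separation per feature is `effect` within-class SDs. Scale features
(STD, Max, |Min|, and KRT) are log-normal around magnitudes typical of
averaged 10-s epochs; Var, MOM and POW are derived (Var = STD²,
MOM = KRT·Var², POW = N²(Var + Mean²) with N = 2560) so the package's
internal identities approximately hold on synthetic rows. Kurtosis loads
*negatively* on severity — large rhythmic activity is platykurtic relative
to background — matching the direction seen in real averaged tables.
`effect = 0` makes the classes identically distributed (chance-level
control).

## Problem sizes and defaults

End-to-end evaluations in the test suite and acceptance script use five
seeded records of 1010 s (five 100-s seizures), i.e. ~50 seizure and ~51
normal epochs per record — enough for stable pooled 5-fold estimates while
keeping a full run in tens of seconds. Headline defaults: window 10 s,
top-k 3, K = 5 folds, moment order 4, entropy 100 bins/natural log, filter
threshold z = 3, SVM C = 1, KNN k = 5, ensemble 100 trees.

## Known limitations

* The entropy feature cannot be validated against any published per-channel
  value (see above); cross-study comparisons of ENT require agreeing on the
  histogram.
* EDF writing stores 16-bit quantized amplitudes (as clinical recorders
  do); round-trips are exact only to the stored scale factor. The built-in
  writer emits minimal single-data-record EDF, not EDF+ (no embedded event
  annotations — the sidecar CSV carries them).
* Mixed per-channel sampling rates in EDF are rejected rather than
  resampled.
* The random protocol draws epochs without overlap; evaluation numbers on
  records barely large enough for the request will use nearly-tiled, hence
  less independent, placements.
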