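# Methods

`typescreen` implements an end-to-end screening method that discriminates
subjects with depressive tendency (DT, PHQ-9 ≥ cutoff) from healthy controls
(HC) using only passively captured touchscreen typing. This note documents
the model, its assumptions, the numerical conventions, and what the synthetic
cohort generator does and does not emulate.

## Keystroke dynamics variables

For a typing session of N keys with press/release timestamps `t_n^p`, `t_n^r`
(epoch ms) and key pixel coordinates `(X_n, Y_n)`:

- **Hold time** `HT_n = t_n^r − t_n^p`, n = 1..N (ms).
- **Flight time** `FT_n = t_{n+1}^p − t_n^r`, n = 1..N−1 (ms). Negative when
  the next key is pressed before the previous is released (two-handed
  overlap).
- **Distance** `D_n = sqrt(((ΔX/ppi_x)·25.4)² + ((ΔY/ppi_y)·25.4)²)` (mm),
  using the per-axis screen densities in portrait orientation. In privacy
  mode only `D` is stored; key identity is unrecoverable.
- **Speed** `SP_n = D_n / FT_n` (mm/ms).
- **Press-flight rate** `PFR_n = HT_n / FT_n` (dimensionless). `HT_n` is
  paired with the flight to the *next* key, so SP/PFR are defined over
  n = 1..N−1.

### Conditional filtering

Applied in this order, all thresholds configurable via `FilterConfig`:

1. **Validity**: sessions with fewer than 8 keys are discarded.
2. **Long presses**: `HT > 300 ms` entries are removed (deliberate long
   presses, e.g. accent pickers); the removal cascades to the paired PFR
   entry only.
3. **Pauses and overlap**: `FT > 3000 ms` (keyboard idle on screen) and
   `FT ≤ 0` (overlap; the SP/PFR ratios are meaningless at non-positive FT)
   are removed; each removal cascades to the paired SP and PFR entries.
4. **Per-user session outliers**: for each user, a session whose filtered-FT
   median deviates from the mean of the user's session medians by more than
   3 standard deviations is excluded from feature extraction (e.g. typing
   while walking). With σ = 0 or fewer than two sessions nothing is flagged.

Filtering is idempotent by construction: the `DynamicsSequences` container
keeps boolean masks over the raw index space and the filtered views are
derived properties.

## Session feature vector (20 dimensions)

Each surviving session is summarised by median, standard deviation, skewness
and kurtosis of each of HT, FT, SP, PFR, plus four metadata values: duration
T (s, keyboard launch to last key release — the raw schema has no explicit
keyboard-close timestamp, so the last release stands in for it), character
count L (deletes excluded), delete rate DR (delete presses over all key
presses) and characters per minute CPM = L/(T/60). The canonical order is
`ht_median, ht_std, ht_skew, ht_kurt, ft_*, sp_*, pfr_*, t_s, l_chars, dr,
cpm`.

Numerical conventions, chosen for fidelity to the method as published:

- median: midpoint rule on the ascending-sorted sequence (1-based ceil/floor
  indexing);
- std: population standard deviation;
- skewness/kurtosis: standardized third/fourth moments with an `N+1`
  denominator (the method's native convention). `standard_moments=True`
  switches to the conventional `N`. The difference is a per-sequence scalar
  and cannot change any rank-based downstream result.
- A variable with fewer than 4 surviving values makes the session incomplete
  (kurtosis needs spread); incomplete sessions are skipped and counted.
- Skew/kurt of a zero-variance sequence are reported as 0.

## Classification pipeline

Leave-one-subject-out (LOSO) over subjects; the decision unit is the subject,
scored by the arithmetic mean of their session probabilities. Per iteration:

1. **Balancing**: majority-class training *sessions* are randomly
   under-sampled to the minority count (seeded). Quotas are allocated
   proportionally per subject so no training subject is silently dropped.
2. **Nested 5-fold CV**: folds are grouped by subject (no subject straddles
   folds) and stratified by class via a seeded round-robin deal. Per fold:
   select the k = 5 best features by ANOVA F on the fold-training portion,
   then grid-search classifier hyperparameters maximising the held-out
   fold's AUC computed on *subject-mean* probabilities (the tuning objective
   matches the reported metric). The (features, hyperparameters) pair of the
   fold with the highest held-out AUC wins (ties: lowest fold index). A
   conventional mean-across-folds mode is available
   (`winner_fold_rule=False`), as is session-level folding
   (`subject_folds=False`) for comparison experiments.
3. **Final fit**: standardization (fit on training rows only) plus the
   classifier, trained on all balanced training rows restricted to the
   selected features. Constant features are dropped with a warning.
4. **Prediction**: probability per held-out session, averaged into the
   subject score; DT iff the score is at or above the decision threshold
   (0.5 by default; the Youden threshold is available from the results).

Classifiers: random forest (default; impurity importances exposed), gradient
boosting, and RBF SVM (standardization matters here; probability outputs via
the built-in Platt-style calibration). Default grids are deliberately small —
random forest: trees {100, 300} × depth {∞, 5, 10}; gradient boosting:
learning rate {0.05, 0.1} × stages {100, 300}; SVM: C {0.1, 1, 10} — the
method as published names no grids.

A leakage guard asserts per iteration that the held-out subject's rows are
disjoint (by row identity) from every row used in balancing, selection,
tuning and fitting; the per-iteration training row ids are retained in the
results for external auditing.

## Evaluation

- **AUC**: rank (Mann-Whitney) formulation, ties counted half.
- **Bootstrap ROC**: subjects (not sessions) resampled with replacement,
  1,000 replicates by default; single-class replicates redrawn; mean curve by
  vertical averaging of TPR on a fixed 101-point FPR grid; 95% CI from the
  2.5/97.5 AUC percentiles.
- **Operating point**: Youden's J = sensitivity + specificity − 1 maximised
  over observed score cutpoints under equal misclassification cost (ties:
  higher sensitivity, then lower threshold).
- **Group comparisons**: two-sided Mann-Whitney U per feature on per-subject
  session means; exact null for group sizes ≤ 12 without ties, otherwise the
  tie-corrected normal approximation. Raw p-values by default (matching the
  method's presentation); Benjamini-Hochberg behind a flag.
- **PHQ-9 correlation**: Spearman rank correlation of subject scores (or any
  per-subject value) against compound PHQ-9 scores.
- **Covariate check**: maximum-likelihood logistic regression of group status
  on prediction probability, age, education, gender, convergence count and
  sessions/day (constant + 6 coefficients, Wald z tests); perfect separation
  is flagged and a weakly regularized fit reported.

## Convergence and daily trajectories

The convergence count is the smallest n such that every cumulative mean of
the chronological session probabilities from n onwards stays within a
tolerance (0.05) of the final mean — i.e. how many sessions are needed before
the screening score is stable. Daily trajectories aggregate session
probabilities per calendar day (UTC); the daily-variability analysis
correlates, across subjects, the standard deviation of daily means with the
mean daily session count.

## Synthetic cohort generator

Real cohorts of this kind cannot be shared, so `CohortSpec`/`generate_cohort`
produce raw event streams with the structure the pipeline assumes. Defaults
encode the emulated study conditions: 11 DT / 14 HC subjects; PHQ-9 compound
scores drawn around group means 10.64 (DT, range 5-15) and 2.29 (HC, range
0-4) and spread over items; sessions per day Poisson with means 55.14 (DT) /
66.46 (HC); ~16 keys per session; key coordinates uniform on a content-free
10×4 grid with 6 mm pitch at 400 ppi.

Timing model: HT and FT are log-normal (positive, right-skewed, the standard
choice for typing latencies) with medians 90 ms (HC HT), 350 ms (FT) and
key-level log-sds 0.25/0.35. Three nested random-effect levels make the data
realistically non-exchangeable: subject level (log-sd 0.12/0.15 — typing
speed is a stable trait, which is what makes LOSO non-trivial), day level
(log-sd 0.08) and session level (log-sd 0.15/0.20 — context, posture, time
of day). Overlap events (negative FT, probability 0.04), pauses > 3 s
(0.03), long presses (0.02) and deletes (rate 0.08) are injected per key;
event injection uses a single uniform draw so the realized negative-FT
fraction equals the configured probability exactly in expectation. Integer
rounding guards keep press and release sequences strictly increasing.

The planted group effect mirrors the direction the method is meant to
detect: the DT hold-time median is raised by 40 ms by default (psychomotor
retardation slows key presses) and the DT SP/PFR dispersion is scaled 1.5×
(`plant_effect` sets both). The dispersion multiplier scales the key-level
log-sds by a factor solved numerically so that the log-normal PFR standard
deviation grows *linearly* with the multiplier.

What the generator does **not** emulate: linguistic content and key
identity, autocorrect/word prediction, circadian session timing, device
heterogeneity, drift of the effect over the study, or label noise near the
PHQ-9 cutoff. Passing tests therefore demonstrate that the pipeline recovers
a planted psychomotor effect of plausible size under realistic nesting and
noise — not that the effect exists in any real population.

## Problem sizes and test design

Simulated checks run at deliberately modest scale so the full suite stays
desk-friendly: pipeline tests use 20-subject cohorts (9 DT / 11 HC, two
study days, ~6 sessions/day, ~110-210 feature rows) and a single-point
random-forest grid. Null calibration uses 4 generator seeds × 13 label
permutations (52 LOSO runs); its grand-mean subject-level AUC is expected in
[0.45, 0.55] — note that a *single* 20-subject permutation AUC has null sd
≈ 0.13, so individual permutations legitimately range far wider. Planted-
effect recovery uses 10 seeds (median AUC > 0.85; HT median consistently
selected), and the shift sweep (0/15/40 ms, dispersion pinned at 1) checks
that AUC is non-decreasing in the planted shift. `scripts/acceptance.py`
runs the default 25-subject cohort over two study days (~3,000 sessions)
with a reduced grid (100 trees, depth {∞, 5}).

## Known limitations

- The LOSO permutation null on small clustered cohorts sits slightly below
  0.5 (the well-documented depletion effect of holding a subject's class
  out); with the generator's noise structure the residual bias is within a
  few hundredths.
- The winner-fold rule is high-variance by construction; the mean-across-
  folds mode is the stabler (but less faithful) alternative.
- T is measured to the last key release, so idle tail time before keyboard
  close is not included; CPM is correspondingly slightly optimistic.
- The exact Mann-Whitney null is skipped in the presence of ties even for
  small groups (falls back to the corrected normal approximation).
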