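# Methods

## The model

`fcmvpa` implements task-based functional-connectivity decoding. The unit of
analysis is an undirected, weighted connectivity map: for a parcellation with
*n* nodes, the Pearson correlation *r_ij* between the denoised ROI-mean BOLD
series of nodes *i* and *j*, computed over the scans attributable to one
experimental condition and variance-stabilised with the Fisher transform
*z = atanh(r)*. The strict lower triangle of this matrix, in row-major order,
is the fixed feature space of *n(n−1)/2* edges (30,135 for *n* = 246). A
per-subject, per-condition feature vector is one sample; leave-one-subject-out
cross-validation (LOOCV) with per-fold feature selection and a linear
soft-margin SVM estimates how well condition labels can be decoded from these
patterns, and label-permutation testing calibrates the significance of the
resulting accuracy.

## Pipeline stages and their assumptions

**Denoising.** Each run's ROI series is regressed (OLS) on an intercept, the
six rigid-body motion parameters, the supplied nuisance components
(physiological/CompCor-style regressors are accepted as given, not computed),
a centred first-order linear trend, and the HRF-convolved task regressors of
every condition; the task columns ensure residual correlations reflect
connectivity, not shared stimulus-evoked co-activation. Residuals are then
band-passed to 0.01–0.1 Hz with a zero-phase order-4 Butterworth filter
(forward–backward). Regression and filtering are per run; runs are never
concatenated before denoising, which avoids filter transients at run
boundaries. The filter family and order are a design choice — the attenuation
contract (≥ 20 dB outside the band, < 10 % amplitude error inside) is what is
tested, not the coefficients.

A note on an orthogonality caveat: the pre-filter OLS residual is exactly
orthogonal to every confound column, but the *filtered* residual is not, and
cannot be made so by any sequential regress-then-filter scheme — a
band-limited series has roughly 0.36 × n_scans effective degrees of freedom
at TR = 2 s, so re-fitting ~20 regressors to it explains substantial variance
by chance alone. The test suite therefore checks the scientific contract
(injected motion-coupled variance is removed to chance-level correlation)
rather than a literal zero-coefficient condition.

**Condition scan assignment.** A scan belongs to a condition when that
condition's HRF-convolved boxcar exceeds a small threshold (1e-6) *and* is
the maximum across conditions. The argmax tie-break guarantees pairwise
disjoint condition scan sets despite HRF spill-over between neighbouring
blocks. Scans are pooled across runs before correlating (pooled-scan
correlation, not the average of per-run correlations). Unweighted pooling is
used; weighting scans by regressor amplitude is deliberately out of scope.

**Feature selection (per fold, training subjects only).** The default
positive-FC rule keeps edges whose Fisher-z values are significantly greater
than zero across training subjects — one-sample t with *t* > 0 and a
Benjamini–Hochberg FDR threshold *q* = 0.01 on the two-sided p (a switch
halves the p for a literal one-sided test) — unioned over the decoded
conditions, i.e. an edge survives if significantly positive for at least one
condition. The rationale is the contested interpretability of negative FC.
The alternative rule ranks edges by a class-separability score (two classes:
Fisher criterion ((m₁−m)² + (m₂−m)²)/(s₁² + s₂²); three or more: one-way
ANOVA F) and keeps the top *k*; when *k* is unset it defaults to the size of
the positive-union mask on the same fold so the two rules are comparable.

**Classification.** One binary soft-margin linear SVM (libsvm backend,
cost C = 1, no inner tuning loop) per class pair on the selected edges.
Multi-class predictions use one-against-one majority voting; vote ties are
broken by the summed signed decision values toward each class, then by
class order. Accuracy is the fraction of correct (subject, condition)
predictions pooled over all folds; chance is 1/|classes|.

**Permutation inference.** Condition labels are shuffled within each subject
(preserving the per-subject class multiset, hence exchangeability under
LOOCV) and the entire pipeline — including per-fold selection — reruns per
permutation. Default p-value is the add-one estimator
(1 + #{null ≥ obs})/(n_perm + 1), valid at any n_perm and never zero; a
`strict` rule implements the plain #{null > obs}/n_perm count.

**Networks.** Edges selected in *every* fold (consensus) are ranked by mean
absolute SVM weight across folds; the top-k (default 50) form a pairwise
contrast's discriminative network. A condition-preferring network is the
intersection of the top-k edge sets of the two pairwise contrasts involving
that condition (weight = mean of the two), matching the "reliable in both
contrasts" reading; an alternative — intersecting consensus sets instead of
top-k sets — is available by passing larger k. Edges are annotated by atlas
module (frontal, temporal, parietal, insula, limbic, occipital, subcortical)
and exported as long-format TSV or viewer .node/.edge text files, with node
size equal to within-network degree.

## The synthetic-data generator

The generator emulates a slow block paradigm: by default 3 emotions × 3
stimulus types × 2 repetitions per run (18 blocks), 8 trials of 2 s + 0.5 s
ISI per block (20 s stimulus span), a 2 s post-block button task, 10 s
fixation intervals, TR = 2 s. Block orders are pseudo-random with neither
emotion nor stimulus type repeating consecutively, sampled by randomized
backtracking (uniform over locally feasible continuations with restarts);
plain permutation rejection is hopeless when a two-level attribute must
strictly alternate. Note that the ordering constraint makes designs with a
single stimulus type (and more than one block) infeasible by construction,
and 2 × 2 designs likewise; reduced test designs therefore keep 3 emotions
and 2 stimulus types.

ROI signals are drawn scan-wise from a multivariate normal: the base
covariance during rest, a condition-perturbed covariance while that
condition's HRF-convolved regressor dominates. Perturbations are
correlation increments on named edges and constitute the recoverable ground
truth; base and all perturbed matrices are verified positive-definite.
Added on top: HRF-convolved activation (per-ROI gains), motion artifact
(six Gaussian random walks, step SD 0.015, coupled to ROIs with loading SD
0.4 — walk magnitudes over a ~300-scan run land in the 0.1–0.3 mm/deg range
typical of compliant adults), a per-ROI linear drift (slope uniform in
±0.8 signal units per run), shared smoothed nuisance components (10 by
default, loading SD 0.3), and white thermal noise (SD 0.5). The exact motion
and nuisance traces are returned as the confound matrix, so confound
regression can remove precisely what was injected.

The default base covariance for studies is block-structured: ROIs split into
4 communities with within-community correlation 0.5 — typical of real
within-network FC and necessary for the positive-FC selection step to have
real work under the null (with weaker correlations or fewer scans per
condition the q = 0.01 selection is legitimately empty and the pipeline
stops). Between-subject effect-size variability defaults to zero: every
subject shares the ground-truth covariance, which is a simplification, not
an empirical claim.

What the generator does *not* emulate: voxel-level structure and spatial
smoothing, temporal autocorrelation of the neural signal (scans are
conditionally independent given the covariance state), scanner physics,
inter-subject anatomical variability, or realistic effect heterogeneity.
Passing calibration and recovery tests therefore demonstrates correctness of
the machinery under the stated generative model — not expected performance
on real data.

## Problem sizes used in tests and the acceptance script

Calibration studies run at desk scale, chosen once as the package's study
conditions: null-calibration cohorts of 12 subjects × 60 ROIs (2 runs of
3 emotions × 2 types × 2 repetitions, 40 scans per condition cell) with 99
permutations; type-I-error replicates of 10 subjects × 30 ROIs, two-class decoding,
n_perm = 49, 200 replicates (accuracy granularity 1/20 limits the tie-induced
conservatism of the discrete permutation p); parameter recovery at 20
subjects × 60 ROIs with the full-depth design (3 runs × 2 repetitions, 60
scans per condition cell) and +0.4 increments on 20 node-disjoint edges.
The full-size
configuration (20 subjects, 246 ROIs, 1000 permutations) runs through the
same API unchanged.

At n_perm = 49 the add-one p can fall below 0.05 only when the observed
accuracy strictly exceeds all 49 null accuracies (p = 0.02), so the nominal
attainable type-I rate is 4 %, and ties in the discrete accuracy
distribution push the realised rate slightly lower — the test brackets it
at 5 ± 3 %.

## Numerical choices

- Correlations are clipped to ±(1 − 1e−7) before `atanh`; the diagonal of a
  connectivity map is 0 by convention and never enters the feature space.
- Zero-variance ROIs yield r = 0 on all their pairs, with a warning.
- Degenerate one-sample t: zero variance with zero mean → t = 0, p = 1;
  zero variance with nonzero mean → signed infinite t, p = 0.
- Score ranking ties are broken by ascending edge index (stable sort);
  top-k weight ties at the cut keep the lower edge index.
- Condition cells are keyed `emotion|stimulus_type` and ordered
  lexicographically everywhere.
- Per-subject simulation seeds are spawned from the master seed
  (`SeedSequence.spawn`), so cohorts are reproducible end to end and
  subjects are independent.

## Known limitations

- The permutation loop refits selection and SVMs per fold per shuffle;
  1000-permutation runs at full size are minutes-to-hours, not seconds.
- The generator's covariance switching changes correlation instantaneously
  at condition boundaries rather than convolving second-order structure
  with the HRF.
- `accuracy_curve` recomputes the per-fold t-test ranking for every k
  rather than caching across the grid.
- No NIfTI ingestion: the pipeline starts at ROI-mean time series (TSV).
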