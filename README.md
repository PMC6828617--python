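# fcmvpa

Functional-connectivity multivariate pattern analysis (fcMVPA) for
block-design task fMRI, starting from ROI-level BOLD time series: confound
regression and band-pass filtering, per-condition ROI-to-ROI Fisher-z
connectivity maps, leave-one-subject-out linear-SVM decoding of experimental
conditions with per-fold feature selection, permutation-based significance,
and construction of discriminative / condition-preferring edge networks. A
synthetic cohort generator with known connectivity ground truth makes every
stage testable without any imaging data.

It is written for researchers who ask whether large-scale connectivity
patterns — rather than regional activation — carry information about task
conditions (e.g. which emotion a participant is viewing), and who want a
calibrated, auditable implementation of the standard pipeline.

## The method in brief

For parcellation nodes *i, j* and condition *c*, the feature is the Fisher-z
correlation of denoised ROI-mean series over the scans assigned to *c*:

    z_ij(c) = atanh( corr(x_i, x_j | scans of c) )

The strict lower triangle gives *n(n−1)/2* edge features per subject and
condition (30,135 for a 246-node atlas). Per LOOCV fold, edges significantly
positive across training subjects (one-sample t, BH-FDR *q* = 0.01, pooled
over conditions) are selected; a linear SVM (C = 1) is trained per class
pair and multi-class predictions use one-against-one voting. Significance of
the accuracy comes from rerunning the whole pipeline under within-subject
label shuffles: p = (1 + #{null ≥ observed})/(n_perm + 1). Edges selected in
every fold are ranked by mean |SVM weight|; the top-50 form a contrast's
discriminative network, and edges discriminative in both contrasts
involving one condition form its condition-preferring network.

## Worked example

```python
import fcmvpa as f

# paradigm: 2 runs x (3 emotions x 2 stimulus types x 2 repetitions)
design = f.make_design(n_runs=2, stimulus_types=("face", "body"),
                       repetitions=2, seed=21)

# ground truth: fear strengthens 10 node-disjoint edges by +0.4 correlation
n_rois = 40
effect = f.EffectSpec(
    n_rois=n_rois,
    base_covariance=f.blocked_correlation(n_rois),
    condition_deltas={"fear": [(e, 0.4) for e in f.disjoint_edges(10, n_rois)]},
)
cohort = f.simulate_cohort(12, design, effect, f.NoiseSpec(), seed=21)

X, conds, subs = f.cohort_features(cohort, design, "face")
keys = [f.condition_key(c, "face") for c in conds]
multi = f.loocv_decode(X, keys, keys)
pair = f.loocv_decode(X, keys, ("anger|face", "fear|face"))
print(multi.accuracy, pair.accuracy)
```

Output:

```
0.6111111111111112 0.8333333333333334
```

Three-class accuracy 61.1 % (chance 33.3 %) and anger-vs-fear accuracy
83.3 % (chance 50 %): the fear maps are separable because only fear carries
the injected edges, while anger vs joy stays at chance (50.0 % on this
seed). The scripts in `examples/` walk through each capability —
simulation, denoising + connectivity, decoding, permutation testing, and
network construction — and print what every number means.

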