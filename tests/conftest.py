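import numpy as np
import pytest

import fcmvpa as f


@pytest.fixture(scope="session")
def small_design():
    """2 runs x (3 emotions x 2 stimulus types x 1 repetition)."""
    return f.make_design(
        n_runs=2, stimulus_types=("face", "body"), repetitions=1, seed=123
    )


@pytest.fixture(scope="session")
def null_features_small():
    """Null cohort (no condition effects): 8 subjects, 30 ROIs.

    Returns (features, condition_keys, subject_ids)."""
    X, conds, subs = f.null_cohort_features(n_subjects=8, n_rois=30, seed=2024)
    keys = [f.condition_key(c, "face") for c in conds]
    return X, keys, subs


def separable_features(n_subj=10, n_edges=200, n_signal=12, delta=1.5, seed=0):
    """Synthetic feature arrays (no simulation) with a clean class signal.

    Class-specific mean shifts on disjoint positive-edge groups give
    linearly separable (subject x class) samples; baseline mean is positive
    so the positive-FC selection keeps the signal edges.
    """
    rng = np.random.default_rng(seed)
    classes = ["a", "b", "c"]
    X = rng.normal(0.4, 0.15, size=(n_subj, len(classes), n_edges))
    for k in range(len(classes)):
        lo = k * n_signal
        X[:, k, lo:lo + n_signal] += delta
    return X, classes
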