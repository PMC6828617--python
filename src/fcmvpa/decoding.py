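"""Edge selection and leave-one-subject-out decoding of condition labels.

Samples are per-subject, per-condition connectivity feature vectors. In each
leave-one-subject-out fold, feature selection runs on the training subjects
only (no peeking): either the positive-FC rule — edges whose Fisher-z values
are significantly greater than zero across training subjects (one-sample t,
Benjamini-Hochberg FDR q = 0.01) in at least one condition — or a top-k cut
of a Fisher-criterion / ANOVA F score ranking. A soft-margin linear support
vector machine (libsvm, C = 1) is trained per class pair on the selected
edges; multi-class predictions use one-against-one majority voting. Overall
accuracy is the fraction of correct (subject, condition) predictions across
all folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SelectionConfig",
    "FoldResult",
    "DecodingResult",
    "one_sample_t",
    "bh_fdr",
    "positive_union_mask",
    "f_scores",
    "f_score_rank",
    "train_linear_classifier",
    "loocv_decode",
    "accuracy_curve",
]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def one_sample_t(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and two-sided p for mean different from zero.

    t = mean / (sd / sqrt(n)) with the n-1 sample standard deviation.
    Degenerate edges: zero variance with zero mean gives t = 0, p = 1; zero
    variance with nonzero mean gives a signed infinite t with p = 0.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[axis]
    if n < 2:
        raise ValueError("one-sample t needs n >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    mean = v.mean(axis=axis)
    sd = v.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t = np.where(zero_sd & (mean == 0), 0.0, t)
    t = np.where(zero_sd & (mean != 0), np.copysign(np.inf, mean), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return t, p


def bh_fdr(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def positive_union_mask(
    train_features: Mapping[str, np.ndarray], q: float = 0.01, one_sided: bool = False
) -> np.ndarray:
    """Positive-FC edge selection pooled over conditions.

    Per condition (subjects x edges matrix): an edge is selected when its mean
    is positive (t > 0) and survives BH-FDR at level ``q``; the final mask is
    the union over conditions — edges significantly positive for at least one
    condition. ``one_sided=True`` halves the two-sided p before correction.
    """
    masks = []
    for cond, mat in train_features.items():
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 training subjects")
        t, p = one_sample_t(mat)
        if one_sided:
            p = p / 2.0
        masks.append((t > 0) & bh_fdr(p, q))
    union = np.logical_or.reduce(masks)
    if not union.any():
        raise ValueError(
            "positive-FC selection is empty; increase q or provide more data"
        )
    return union


def f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Class-separability score per feature.

    Two classes: Fisher criterion ((m1-m)^2 + (m2-m)^2) / (s1^2 + s2^2) with
    class means m1, m2, overall mean m and within-class sample variances.
    Three or more classes: one-way ANOVA F. Constant features score 0; zero
    within-class variance with distinct means scores +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    groups = [X[y == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 samples per class")
    if len(classes) == 2:
        m = X.mean(axis=0)
        num = sum((g.mean(axis=0) - m) ** 2 for g in groups)
        den = sum(g.var(axis=0, ddof=1) for g in groups)
    else:
        # one-way ANOVA F: between-group / within-group mean squares
        m = X.mean(axis=0)
        num = sum(len(g) * (g.mean(axis=0) - m) ** 2 for g in groups) / (len(classes) - 1)
        den = sum((g - g.mean(axis=0)) ** 2 for g in groups).sum(axis=0) / (
            len(X) - len(classes)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        s = num / den
    s = np.where((den == 0) & (num == 0), 0.0, s)
    s = np.where((den == 0) & (num > 0), np.inf, s)
    return s


def f_score_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature indices sorted by descending score, ties broken by index."""
    s = f_scores(X, y)
    return np.argsort(-s, kind="stable")


class LinearSVM(NamedTuple):
    weights: np.ndarray
    bias: float
    classes: tuple

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Signed distance; positive favors ``classes[1]``."""
        return np.asarray(X) @ self.weights + self.bias


def train_linear_classifier(X: np.ndarray, y: np.ndarray, cost: float = 1.0) -> LinearSVM:
    """Binary soft-margin linear SVM (libsvm backend, default cost 1)."""
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("binary classifier requires exactly 2 classes")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(np.asarray(X, dtype=float), y)
    return LinearSVM(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        classes=tuple(clf.classes_),
    )


# ---------------------------------------------------------------------------
# Leave-one-subject-out decoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionConfig:
    """Feature-selection rule applied independently inside every fold.

    ``positive_fdr``: union of significantly-positive edges over the decoded
    classes at FDR ``q`` (set ``pool_all_conditions`` to pool every condition
    present, not just the decoded ones). ``f_score_topk``: top ``k`` edges of
    the score ranking; ``k=None`` uses the size of the positive-union mask on
    the same fold, making the two rules comparable.
    """

    method: str = "positive_fdr"
    q: float = 0.01
    k: int | None = None
    one_sided: bool = False
    pool_all_conditions: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("positive_fdr", "f_score_topk"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class FoldResult:
    held_out_subject: str
    training_subjects: tuple[str, ...]
    selected_edges: np.ndarray           # indices into the edge feature space
    pair_weights: dict[tuple, LinearSVM]  # one binary SVM per class pair
    true_labels: list
    predicted_labels: list
    correct: list[bool]


@dataclass
class DecodingResult:
    mode: str
    classes: tuple
    fold_results: list[FoldResult]
    accuracy: float
    chance_level: float

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "chance_level": self.chance_level,
            "folds": [
                {
                    "held_out": f.held_out_subject,
                    "selected_edges": [int(e) for e in f.selected_edges],
                    "true": list(f.true_labels),
                    "predicted": list(f.predicted_labels),
                }
                for f in self.fold_results
            ],
        }


def _as_label_matrix(labels, n_subjects: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    if labels.ndim == 1:
        labels = np.tile(labels, (n_subjects, 1))
    return labels


def loocv_decode(
    condition_maps: np.ndarray,
    labels: Sequence | np.ndarray,
    classes: Sequence,
    selection: SelectionConfig = SelectionConfig(),
    cost: float = 1.0,
    subject_ids: Sequence[str] | None = None,
) -> DecodingResult:
    """Leave-one-subject-out decoding.

    ``condition_maps``: array (n_subjects, n_maps_per_subject, n_edges) of
    connectivity feature vectors. ``labels``: condition label per map, either
    one row shared by all subjects or an (n_subjects, n_maps) matrix (used by
    the permutation test). ``classes``: the labels actually decoded — a pair
    for pairwise mode, three or more for one-against-one voting. Selection is
    refit on the training subjects of every fold.
    """
    X = np.asarray(condition_maps, dtype=float)
    if X.ndim != 3:
        raise ValueError("condition_maps must be (subjects, maps, edges)")
    n_subj = X.shape[0]
    if n_subj < 2:
        raise ValueError("need >= 2 subjects for leave-one-out")
    Y = _as_label_matrix(labels, n_subj)
    classes = tuple(sorted(classes))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    missing = set(classes) - set(np.unique(Y).tolist())
    if missing:
        raise ValueError(f"classes absent from labels: {sorted(missing)}")
    return _loocv_core(X, Y, classes, _selection_fn(selection, classes), cost, subject_ids)


def _vote(x: np.ndarray, machines: Mapping[tuple, LinearSVM], classes: tuple):
    """One-against-one majority vote; ties broken by summed decision values
    toward each class, then by class order."""
    votes = {c: 0 for c in classes}
    margin = {c: 0.0 for c in classes}
    for (a, b), svm in machines.items():
        d = float(x @ svm.weights + svm.bias)
        lo, hi = svm.classes  # sorted by the SVM; positive decision favors hi
        votes[hi if d > 0 else lo] += 1
        margin[hi] += d
        margin[lo] -= d
    best = max(votes.values())
    tied = [c for c in classes if votes[c] == best]
    if len(tied) == 1:
        return tied[0]
    best_m = max(margin[c] for c in tied)
    for c in tied:  # classes is sorted: first hit is the class-order tie-break
        if margin[c] == best_m:
            return c


def _selection_fn(selection: SelectionConfig, classes: tuple) -> Callable:
    def positive(X_tr, y_tr):
        conds = (
            sorted(np.unique(y_tr).tolist())
            if selection.pool_all_conditions
            else list(classes)
        )
        per_cond = {c: X_tr[y_tr == c] for c in conds}
        return positive_union_mask(per_cond, q=selection.q, one_sided=selection.one_sided)

    if selection.method == "positive_fdr":
        return positive

    def top_k(X_tr, y_tr):
        k = selection.k
        if k is None:
            k = int(positive(X_tr, y_tr).sum())
        rows = np.isin(y_tr, classes)
        order = f_score_rank(X_tr[rows], y_tr[rows])
        k = min(k, X_tr.shape[1])
        mask = np.zeros(X_tr.shape[1], dtype=bool)
        mask[order[:k]] = True
        return mask

    return top_k


def accuracy_curve(
    condition_maps: np.ndarray,
    labels: Sequence | np.ndarray,
    classes: Sequence,
    k_grid: Sequence[int],
    cost: float = 1.0,
    subject_ids: Sequence[str] | None = None,
) -> list[tuple[int, float]]:
    """Decoding accuracy as a function of the number of edges used.

    Inside each fold, edges are ranked by the smallest across-condition
    one-sample-t p value (ascending) on the training subjects, the top k are
    kept, and decoding proceeds as in :func:`loocv_decode`. k values above
    the feature count are clamped with a warning.
    """
    X = np.asarray(condition_maps, dtype=float)
    n_edges = X.shape[2]
    out = []
    for k in k_grid:
        kk = int(k)
        if kk > n_edges:
            warnings.warn(f"k={kk} exceeds feature count {n_edges}; clamped")
            kk = n_edges

        def select(X_tr, y_tr, kk=kk):
            pmins = None
            for c in classes:
                _, p = one_sample_t(X_tr[y_tr == c])
                pmins = p if pmins is None else np.minimum(pmins, p)
            order = np.argsort(pmins, kind="stable")
            mask = np.zeros(X_tr.shape[1], dtype=bool)
            mask[order[:kk]] = True
            return mask

        res = _loocv_core(
            X, _as_label_matrix(labels, X.shape[0]), tuple(sorted(classes)),
            select, cost, subject_ids,
        )
        out.append((kk, res.accuracy))
    return out


def _loocv_core(X, Y, classes, select_fn, cost, subject_ids):
    n_subj = X.shape[0]
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(n_subj)]
    folds, n_correct, n_total = [], 0, 0
    for s in range(n_subj):
        train = np.arange(n_subj) != s
        X_tr = X[train].reshape(-1, X.shape[2])
        y_tr = Y[train].ravel()
        try:
            sel = select_fn(X_tr, y_tr)
        except ValueError as err:
            raise ValueError(
                f"feature selection failed on fold holding out {subject_ids[s]}: {err}"
            ) from err
        machines = {
            pair: train_linear_classifier(
                X_tr[np.ix_(np.isin(y_tr, pair), sel)],
                y_tr[np.isin(y_tr, pair)],
                cost=cost,
            )
            for pair in combinations(classes, 2)
        }
        true_l, pred_l, corr = [], [], []
        for m in range(X.shape[1]):
            lab = Y[s, m]
            if lab not in classes:
                continue
            pred = _vote(X[s, m, sel], machines, classes)
            true_l.append(lab)
            pred_l.append(pred)
            corr.append(pred == lab)
        n_correct += sum(corr)
        n_total += len(corr)
        folds.append(
            FoldResult(
                held_out_subject=subject_ids[s],
                training_subjects=tuple(subject_ids[i] for i in range(n_subj) if i != s),
                selected_edges=np.flatnonzero(sel),
                pair_weights=machines,
                true_labels=true_l,
                predicted_labels=pred_l,
                correct=corr,
            )
        )
    mode = "pairwise" if len(classes) == 2 else "multi_category"
    return DecodingResult(
        mode=mode,
        classes=classes,
        fold_results=folds,
        accuracy=n_correct / n_total,
        chance_level=1.0 / len(classes),
    )
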