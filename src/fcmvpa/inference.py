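"""Permutation-based significance of decoding accuracy.

The null hypothesis is that condition labels carry no information about the
connectivity patterns. Each permutation shuffles the condition labels within
every subject (preserving the per-subject class multiset and hence
exchangeability under leave-one-subject-out cross-validation) and reruns the
complete decoding pipeline, including per-fold feature selection. The default
p-value uses the add-one estimator p = (1 + #{null >= observed}) / (n_perm + 1),
which is valid for any number of permutations and can never be zero; the
``strict`` rule counts only strict exceedances, #{null > observed} / n_perm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .decoding import DecodingResult, SelectionConfig, _as_label_matrix, loocv_decode

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    rule: str
    chance_level: float

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": self.observed_accuracy,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "rule": self.rule,
            "chance_level": self.chance_level,
            "null_accuracies": [float(a) for a in self.null_accuracies],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def permutation_test(
    condition_maps: np.ndarray,
    labels: Sequence | np.ndarray,
    classes: Sequence,
    selection: SelectionConfig = SelectionConfig(),
    n_perm: int = 1000,
    seed: int | None = None,
    rule: str = "add_one",
    cost: float = 1.0,
    observed: DecodingResult | None = None,
) -> PermutationResult:
    """Label-permutation test of leave-one-subject-out decoding accuracy.

    ``rule="add_one"`` (default): p = (1 + #{null >= obs}) / (n_perm + 1).
    ``rule="strict"``: p = #{null > obs} / n_perm — the literal "fraction of
    permutations exceeding the observed accuracy" counting rule.
    A precomputed observed :class:`DecodingResult` may be passed to avoid
    rerunning the unpermuted decoding.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rule not in ("add_one", "strict"):
        raise ValueError(f"unknown rule {rule!r}")
    X = np.asarray(condition_maps, dtype=float)
    Y = _as_label_matrix(labels, X.shape[0])
    if observed is None:
        observed = loocv_decode(X, Y, classes, selection, cost=cost)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        Yp = np.empty_like(Y)
        for s in range(Y.shape[0]):
            Yp[s] = Y[s, rng.permutation(Y.shape[1])]
        null[b] = loocv_decode(X, Yp, classes, selection, cost=cost).accuracy
    obs = observed.accuracy
    if rule == "add_one":
        p = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    else:
        p = int(np.sum(null > obs)) / n_perm
    return PermutationResult(
        observed_accuracy=obs,
        null_accuracies=null,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        rule=rule,
        chance_level=observed.chance_level,
    )
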