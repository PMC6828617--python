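"""Discriminative and emotion-preferring network construction.

Edges selected by the feature-selection step in every cross-validation fold
(consensus edges) are the reliable discriminative features; each one's
discriminative weight is the mean absolute linear-SVM coefficient across
folds. The top-k (default 50) highest-weight edges form the discriminative
network of a pairwise contrast. An emotion-preferring network contains the
edges discriminative in both pairwise contrasts involving that emotion, with
the mean of the two pairwise weights. Edges are annotated with atlas module
membership (frontal, temporal, parietal, insula, limbic, occipital,
subcortical) to distinguish intra- from inter-module connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import edge_index
from .decoding import DecodingResult

__all__ = [
    "MODULES",
    "NetworkEdge",
    "DiscriminativeNetwork",
    "consensus_mask",
    "discriminative_weights",
    "fold_masks",
    "fold_weight_maps",
    "top_k_network",
    "emotion_preferring_network",
    "export_network",
]

MODULES = (
    "frontal",
    "temporal",
    "parietal",
    "insula",
    "limbic",
    "occipital",
    "subcortical",
)


@dataclass(frozen=True)
class NetworkEdge:
    """One ranked edge: 0-based ROI indices plus atlas annotations."""

    node_a: int
    node_b: int
    weight: float
    module_a: str
    module_b: str
    intra_module: bool


@dataclass
class DiscriminativeNetwork:
    context: str
    edges: list[NetworkEdge]
    k: int

    def __post_init__(self) -> None:
        w = [e.weight for e in self.edges]
        if any(a < b for a, b in zip(w, w[1:])):
            raise ValueError("edges must be sorted by weight descending")
        for e in self.edges:
            if e.intra_module != (e.module_a == e.module_b):
                raise ValueError("intra_module flag inconsistent with modules")

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.node_a, e.node_b) for e in self.edges}

    @property
    def n_intra(self) -> int:
        return sum(e.intra_module for e in self.edges)


def fold_masks(result: DecodingResult) -> list[np.ndarray]:
    """Selected-edge index arrays, one per LOOCV fold."""
    return [f.selected_edges for f in result.fold_results]


def fold_weight_maps(
    result: DecodingResult, pair: tuple | None = None
) -> list[dict[int, float]]:
    """Per-fold {edge index -> SVM coefficient} for one class pair.

    For a pairwise decoding run the pair may be omitted (there is only one
    sub-classifier); for multi-category runs it selects the one-vs-one
    machine of interest.
    """
    maps = []
    for f in result.fold_results:
        if pair is None:
            if len(f.pair_weights) != 1:
                raise ValueError("pair must be given for multi-category results")
            svm = next(iter(f.pair_weights.values()))
        else:
            key = tuple(sorted(pair))
            if key not in f.pair_weights:
                raise KeyError(f"pair {key} not in fold {f.held_out_subject}")
            svm = f.pair_weights[key]
        maps.append(dict(zip((int(e) for e in f.selected_edges), svm.weights)))
    return maps


def consensus_mask(fold_masks: Sequence[Iterable[int]]) -> np.ndarray:
    """Edges selected in every fold (set intersection), sorted ascending."""
    if len(fold_masks) < 1:
        raise ValueError("need at least one fold")
    sets = [set(int(e) for e in m) for m in fold_masks]
    consensus = set.intersection(*sets)
    if not consensus:
        warnings.warn("consensus edge set is empty")
    return np.array(sorted(consensus), dtype=int)


def discriminative_weights(
    fold_weight_maps: Sequence[Mapping[int, float]], consensus: Iterable[int]
) -> dict[int, float]:
    """Mean absolute classifier weight across folds for each consensus edge."""
    out = {}
    for e in consensus:
        e = int(e)
        vals = []
        for m, wm in enumerate(fold_weight_maps):
            if e not in wm:
                raise ValueError(f"consensus edge {e} missing from fold {m} weights")
            vals.append(abs(wm[e]))
        out[e] = float(np.mean(vals))
    return out


def top_k_network(
    weights: Mapping[int, float],
    k: int = 50,
    atlas: pd.DataFrame | None = None,
    n_rois: int | None = None,
    context: str = "",
) -> DiscriminativeNetwork:
    """The k highest-weight edges, ties broken by edge index ascending.

    ``atlas`` is the node table (see :func:`fcmvpa.io.read_atlas`); when
    omitted, module annotations fall back to a single unlabeled module.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not weights:
        raise ValueError("empty weight map")
    if n_rois is None:
        if atlas is None:
            raise ValueError("need atlas or n_rois to resolve edge indices")
        n_rois = len(atlas)
    eidx = edge_index(n_rois)
    order = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(order) < k:
        warnings.warn(f"only {len(order)} edges available for k={k}")
    chosen = order[:k]
    edges = []
    for e, w in chosen:
        i, j = eidx[e]
        if atlas is not None:
            mod_a = atlas.iloc[i]["module"]
            mod_b = atlas.iloc[j]["module"]
        else:
            mod_a = mod_b = "unknown"
        edges.append(
            NetworkEdge(
                node_a=i,
                node_b=j,
                weight=float(w),
                module_a=mod_a,
                module_b=mod_b,
                intra_module=mod_a == mod_b,
            )
        )
    return DiscriminativeNetwork(context=context, edges=edges, k=k)


def emotion_preferring_network(
    pairwise_networks: Mapping[tuple, DiscriminativeNetwork], emotion: str
) -> DiscriminativeNetwork:
    """Edges discriminative in both pairwise contrasts involving ``emotion``.

    The edge set is the intersection of the two pairwise networks' edge sets;
    each edge's weight is the mean of its two pairwise weights.
    """
    involving = {
        tuple(sorted(pair)): net
        for pair, net in pairwise_networks.items()
        if emotion in pair
    }
    if len(involving) != 2:
        raise ValueError(
            f"need the two pairwise networks involving {emotion!r}; "
            f"got {sorted(involving)}"
        )
    (net1, net2) = involving.values()
    common = net1.edge_set & net2.edge_set
    if not common:
        warnings.warn(f"no common discriminative edges for {emotion!r}")
    by_pair1 = {(e.node_a, e.node_b): e for e in net1.edges}
    by_pair2 = {(e.node_a, e.node_b): e for e in net2.edges}
    merged = []
    for ab in common:
        e1, e2 = by_pair1[ab], by_pair2[ab]
        merged.append(
            NetworkEdge(
                node_a=ab[0],
                node_b=ab[1],
                weight=(e1.weight + e2.weight) / 2.0,
                module_a=e1.module_a,
                module_b=e1.module_b,
                intra_module=e1.intra_module,
            )
        )
    merged.sort(key=lambda e: (-e.weight, e.node_a, e.node_b))
    return DiscriminativeNetwork(
        context=f"{emotion}-preferring", edges=merged, k=len(merged)
    )


def export_network(
    net: DiscriminativeNetwork,
    atlas: pd.DataFrame,
    path: str | Path,
    fmt: str = "edge_tsv",
) -> list[Path]:
    """Write a network to disk.

    ``edge_tsv``: long table (node_a_label, node_b_label, weight, module_a,
    module_b, intra). ``viewer``: whitespace-delimited ``.node`` file
    (x y z module_code size=degree label) plus a square symmetric ``.edge``
    weight matrix, the plain-text formats surface viewers import.
    """
    path = Path(path)
    if fmt == "edge_tsv":
        rows = [
            {
                "node_a_label": atlas.iloc[e.node_a]["label"],
                "node_b_label": atlas.iloc[e.node_b]["label"],
                "node_a_id": int(atlas.iloc[e.node_a]["node_id"]),
                "node_b_id": int(atlas.iloc[e.node_b]["node_id"]),
                "weight": e.weight,
                "module_a": e.module_a,
                "module_b": e.module_b,
                "intra": int(e.intra_module),
            }
            for e in net.edges
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return [path]
    if fmt == "viewer":
        n = len(atlas)
        W = np.zeros((n, n))
        degree = np.zeros(n, dtype=int)
        for e in net.edges:
            W[e.node_a, e.node_b] = W[e.node_b, e.node_a] = e.weight
            degree[e.node_a] += 1
            degree[e.node_b] += 1
        node_path = path.with_suffix(".node")
        edge_path = path.with_suffix(".edge")
        mod_code = {m: i + 1 for i, m in enumerate(MODULES)}
        lines = []
        for i in range(n):
            row = atlas.iloc[i]
            lines.append(
                f"{row['mni_x']:.1f}\t{row['mni_y']:.1f}\t{row['mni_z']:.1f}\t"
                f"{mod_code.get(row['module'], 0)}\t{degree[i]}\t{row['label']}"
            )
        node_path.write_text("\n".join(lines) + "\n")
        np.savetxt(edge_path, W, fmt="%.6g", delimiter="\t")
        return [node_path, edge_path]
    raise ValueError(f"unknown export format {fmt!r}")
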