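"""End-to-end orchestration: cohort -> denoise -> connectivity -> decoding ->
permutation significance -> discriminative networks, with a JSON summary.

`cohort_features` is the workhorse used throughout the tests and examples:
it turns a simulated or loaded cohort into the (subjects x conditions x
edges) feature array that the decoding, inference and network stages consume.
"""

from __future__ import annotations

import json
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from . import networks as net
from .connectivity import condition_scan_indices, fc_map, vectorize_lower_triangle
from .decoding import SelectionConfig, loocv_decode
from .denoise import build_task_regressors, denoise_subject
from .inference import permutation_test
from .io import RunConfig, synthetic_atlas, write_atlas
from .synthetic import (
    BlockDesign,
    EffectSpec,
    NoiseSpec,
    SubjectData,
    TimingParams,
    blocked_correlation,
    condition_key,
    make_design,
    simulate_cohort,
    write_dataset,
)

__all__ = ["cohort_features", "null_cohort_features", "run_pipeline"]


def cohort_features(
    cohort: Sequence[SubjectData],
    design: BlockDesign,
    stimulus_type: str,
    conditions: Sequence[str] | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    denoised: bool = False,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-subject, per-condition connectivity feature matrix.

    Each subject's runs are denoised (unless ``denoised=True``), the scans of
    every (condition, ``stimulus_type``) cell are pooled across runs, and the
    Fisher-z map is vectorized. Returns ``(features, conditions, subject_ids)``
    with ``features`` shaped (n_subjects, n_conditions, n_edges).
    """
    if conditions is None:
        conditions = design.conditions
    conditions = sorted(conditions)
    keys = [condition_key(c, stimulus_type) for c in conditions]
    regs = [build_task_regressors(design, run=r) for r in range(design.n_runs)]
    idx_by_run = {
        key: [condition_scan_indices(regs[r], key) for r in range(design.n_runs)]
        for key in keys
    }
    rows = []
    subject_ids = []
    for sub in cohort:
        ds = sub if denoised else denoise_subject(sub, design, low_hz, high_hz)
        row = []
        for key in keys:
            cm = fc_map(ds.timeseries, idx_by_run[key], key, subject_id=sub.subject_id)
            row.append(vectorize_lower_triangle(cm).values)
        rows.append(row)
        subject_ids.append(sub.subject_id)
    return np.asarray(rows), list(conditions), subject_ids


def null_cohort_features(
    n_subjects: int,
    n_rois: int,
    seed: int,
    n_runs: int = 2,
    conditions: Sequence[str] = ("anger", "fear", "joy"),
    stimulus_types: Sequence[str] = ("face", "body"),
    repetitions: int = 2,
    decode_stimulus_type: str = "face",
    rho: float = 0.5,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Features for a cohort with NO condition-specific connectivity effects.

    Convenience wrapper used for calibration studies: block-structured base
    covariance, realistic confounds, empty condition deltas.
    """
    design = make_design(
        n_runs=n_runs,
        conditions=conditions,
        stimulus_types=stimulus_types,
        repetitions=repetitions,
        timing=TimingParams(),
        seed=seed,
    )
    effect = EffectSpec(
        n_rois=n_rois, base_covariance=blocked_correlation(n_rois, rho=rho)
    )
    cohort = simulate_cohort(n_subjects, design, effect, NoiseSpec(), seed=seed)
    return cohort_features(cohort, design, decode_stimulus_type, conditions)


def run_pipeline(config: RunConfig, effect: EffectSpec | None = None) -> dict:
    """Simulate (or load), denoise, decode, test significance, build networks.

    Writes the echoed config, dataset, decoding/permutation JSON and network
    exports under ``config.output_dir``; returns the summary dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

    if config.dataset_dir is not None:
        from .io import read_dataset

        cohort, design = read_dataset(config.dataset_dir)
    else:
        design = make_design(
            n_runs=config.n_runs,
            conditions=config.conditions,
            stimulus_types=config.stimulus_types,
            repetitions=config.repetitions,
            timing=TimingParams(),
            seed=config.seed,
        )
        if effect is None:
            effect = EffectSpec(
                n_rois=config.n_rois,
                base_covariance=blocked_correlation(config.n_rois),
            )
        cohort = simulate_cohort(
            config.n_subjects, design, effect, NoiseSpec(), seed=config.seed
        )
        write_dataset(out / "dataset", cohort, design, effect)

    X, conditions, subject_ids = cohort_features(
        cohort,
        design,
        config.decode_stimulus_type,
        low_hz=config.low_hz,
        high_hz=config.high_hz,
    )
    selection = SelectionConfig(
        method=config.selection_method, q=config.q, k=config.k
    )
    keys = [condition_key(c, config.decode_stimulus_type) for c in conditions]

    multi = loocv_decode(X, keys, keys, selection, cost=config.cost,
                         subject_ids=subject_ids)
    perm = permutation_test(
        X, keys, keys, selection, n_perm=config.n_perm,
        seed=config.seed, rule=config.perm_rule, cost=config.cost,
        observed=multi,
    )

    # recover node count from the edge count: E = n(n-1)/2
    n_rois = int((1 + np.sqrt(1 + 8 * X.shape[2])) / 2)
    if config.atlas_path is not None:
        from .io import read_atlas

        atlas = read_atlas(config.atlas_path)
    else:
        atlas = synthetic_atlas(n_rois, seed=config.seed)
        write_atlas(atlas, out / "atlas_synthetic.tsv")

    pairwise = {}
    pair_nets = {}
    for pair in combinations(keys, 2):
        res = loocv_decode(X, keys, pair, selection, cost=config.cost,
                           subject_ids=subject_ids)
        pairwise[pair] = res
        consensus = net.consensus_mask(net.fold_masks(res))
        if consensus.size:
            weights = net.discriminative_weights(net.fold_weight_maps(res), consensus)
            network = net.top_k_network(
                weights, k=config.network_k, atlas=atlas,
                context=f"{pair[0]}_vs_{pair[1]}",
            )
            pair_nets[pair] = network
            name = f"network_{pair[0]}_vs_{pair[1]}.tsv".replace("|", "-")
            net.export_network(network, atlas, out / name)

    preferring = {}
    if len(pair_nets) == len(pairwise) and len(keys) >= 3:
        for emo in keys:
            try:
                pnet = net.emotion_preferring_network(pair_nets, emo)
            except ValueError:
                continue
            preferring[emo] = pnet
            name = f"network_{emo}_preferring.tsv".replace("|", "-")
            net.export_network(pnet, atlas, out / name)

    summary = {
        "seed": config.seed,
        "conditions": keys,
        "n_subjects": len(subject_ids),
        "n_edges": int(X.shape[2]),
        "multi_category_accuracy": multi.accuracy,
        "chance_level": multi.chance_level,
        "permutation_p": perm.p_value,
        "permutation_null_mean": float(np.mean(perm.null_accuracies)),
        "pairwise_accuracy": {
            f"{a} vs {b}": r.accuracy for (a, b), r in pairwise.items()
        },
        "preferring_network_sizes": {e: len(n.edges) for e, n in preferring.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    perm.to_json(out / "permutation.json")
    (out / "decoding.json").write_text(json.dumps(multi.to_dict(), indent=1))
    return summary
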