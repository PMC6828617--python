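"""Synthetic multi-subject block-design ROI BOLD with known connectivity effects.

The generator emulates a slow event/block paradigm: runs of stimulus blocks
(emotion x stimulus type) separated by fixation, sampled at a fixed TR. ROI
signals are drawn scan-wise from a multivariate normal whose covariance is the
base (resting) covariance, switched to a condition-perturbed covariance while
that condition's HRF-convolved regressor dominates. On top of the neural
signal it layers HRF-convolved activation, motion-coupled artifact from six
random-walk motion traces, a per-run linear drift, shared nuisance components
with per-ROI loadings, and white thermal noise. The exact motion and nuisance
traces used are returned as the confound matrix, so downstream confound
regression can remove precisely what was injected.

Simulation operates at the ROI level (no voxels): every downstream stage of
the pipeline consumes ROI-mean series, so voxel synthesis would add cost
without exercising any additional code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimingParams",
    "Block",
    "BlockDesign",
    "EffectSpec",
    "NoiseSpec",
    "SubjectData",
    "canonical_hrf",
    "make_design",
    "condition_key",
    "condition_regressors",
    "blocked_correlation",
    "disjoint_edges",
    "simulate_subject",
    "simulate_cohort",
    "write_dataset",
]

DEFAULT_HRF_DURATION_S = 32.0


@dataclass(frozen=True)
class TimingParams:
    """Block timing. Defaults follow a 2 s TR slow block paradigm:
    8 trials of a 2 s stimulus + 0.5 s ISI (20 s stimulus span), a 2 s
    post-block button task, and 10 s fixation before each block."""

    tr: float = 2.0
    n_trials: int = 8
    trial_dur_s: float = 2.0
    isi_s: float = 0.5
    fixation_s: float = 10.0
    post_block_task_s: float = 2.0

    @property
    def stimulus_span_s(self) -> float:
        return self.n_trials * (self.trial_dur_s + self.isi_s)


@dataclass(frozen=True)
class Block:
    condition_label: str
    stimulus_type: str
    onset_s: float
    n_trials: int
    trial_dur_s: float
    isi_s: float
    post_block_task_s: float

    @property
    def duration_s(self) -> float:
        """Stimulus span of the block (trials + ISIs), excluding the button task."""
        return self.n_trials * (self.trial_dur_s + self.isi_s)


@dataclass
class BlockDesign:
    """Timed blocks per run plus the sampling grid (TR, scans per run)."""

    tr: float
    runs: list[list[Block]]
    fixation_s: float
    n_scans_per_run: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        run_len_s = self.n_scans_per_run * self.tr
        for r, blocks in enumerate(self.runs):
            prev_end = -np.inf
            for b in blocks:
                if b.onset_s < prev_end:
                    raise ValueError(f"run {r}: overlapping/unordered blocks")
                prev_end = b.onset_s + b.duration_s
                if prev_end > run_len_s + 1e-9:
                    raise ValueError(f"run {r}: block exceeds run length")
            for a, b in zip(blocks, blocks[1:]):
                if a.condition_label == b.condition_label:
                    raise ValueError(f"run {r}: consecutive blocks share condition")
                if a.stimulus_type == b.stimulus_type:
                    raise ValueError(f"run {r}: consecutive blocks share stimulus type")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def conditions(self) -> list[str]:
        return sorted({b.condition_label for blocks in self.runs for b in blocks})

    @property
    def stimulus_types(self) -> list[str]:
        return sorted({b.stimulus_type for blocks in self.runs for b in blocks})

    @property
    def condition_keys(self) -> list[str]:
        return sorted(
            {condition_key(b.condition_label, b.stimulus_type) for blocks in self.runs for b in blocks}
        )

    def to_dict(self) -> dict:
        return {
            "tr": self.tr,
            "fixation_s": self.fixation_s,
            "n_scans_per_run": self.n_scans_per_run,
            "runs": [
                [
                    {
                        "condition_label": b.condition_label,
                        "stimulus_type": b.stimulus_type,
                        "onset_s": b.onset_s,
                        "n_trials": b.n_trials,
                        "trial_dur_s": b.trial_dur_s,
                        "isi_s": b.isi_s,
                        "post_block_task_s": b.post_block_task_s,
                    }
                    for b in blocks
                ]
                for blocks in self.runs
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BlockDesign":
        runs = [[Block(**b) for b in blocks] for blocks in d["runs"]]
        return cls(
            tr=d["tr"],
            runs=runs,
            fixation_s=d["fixation_s"],
            n_scans_per_run=d["n_scans_per_run"],
        )


def condition_key(condition_label: str, stimulus_type: str) -> str:
    """Canonical key for one (emotion, stimulus type) cell, e.g. ``fear|face``."""
    return f"{condition_label}|{stimulus_type}"


def canonical_hrf(tr: float, duration: float = DEFAULT_HRF_DURATION_S) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr``.

    Standard parameters: response peak delay 6 s, undershoot delay 16 s, both
    dispersions 1 s, undershoot ratio 1/6. The kernel is normalised to unit
    peak; its value at t=0 is 0 and its maximum lies near 5 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < tr:
        raise ValueError("duration must be at least one TR")
    n = int(np.ceil(duration / tr))
    t = np.arange(n) * tr
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def make_design(
    n_runs: int = 3,
    conditions: Sequence[str] = ("anger", "fear", "joy"),
    stimulus_types: Sequence[str] = ("face", "body", "person"),
    repetitions: int = 2,
    timing: TimingParams = TimingParams(),
    seed: int | None = None,
    max_tries: int = 5000,
) -> BlockDesign:
    """Pseudo-random block order per run: each run holds
    ``len(conditions) * len(stimulus_types) * repetitions`` blocks and neither
    the emotion nor the stimulus type repeats between consecutive blocks.

    With the defaults this is 18 blocks per run (3 emotions x 3 types x 2
    repetitions). Orders are rejection-sampled; an unsatisfiable request
    (e.g. a single condition or type with more than one block) raises.
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if seed is None:
        raise ValueError("seed is required for a reproducible design")
    cells = [
        (c, s) for c in conditions for s in stimulus_types for _ in range(repetitions)
    ]
    n_blocks = len(cells)
    if n_blocks > 1 and (len(conditions) < 2 or len(stimulus_types) < 2):
        raise ValueError(
            "ordering constraint unsatisfiable: with a single condition or a "
            "single stimulus type consecutive blocks must repeat it"
        )
    rng = np.random.default_rng(seed)
    runs: list[list[Block]] = []
    for _ in range(n_runs):
        order = _sample_order(cells, rng, max_tries)
        t = timing.fixation_s
        blocks = []
        for cond, stype in order:
            blocks.append(
                Block(
                    condition_label=cond,
                    stimulus_type=stype,
                    onset_s=t,
                    n_trials=timing.n_trials,
                    trial_dur_s=timing.trial_dur_s,
                    isi_s=timing.isi_s,
                    post_block_task_s=timing.post_block_task_s,
                )
            )
            t += timing.stimulus_span_s + timing.post_block_task_s + timing.fixation_s
        runs.append(blocks)
    n_scans = int(np.ceil(t / timing.tr))
    return BlockDesign(
        tr=timing.tr, runs=runs, fixation_s=timing.fixation_s, n_scans_per_run=n_scans
    )


def _sample_order(cells, rng, max_tries):
    """Randomized backtracking: place cells one by one, choosing uniformly
    among the remaining cells compatible with the previous block (different
    condition AND different stimulus type); restart on dead ends."""
    cells = list(cells)
    n = len(cells)
    for _ in range(max_tries):
        remaining = cells.copy()
        perm: list = []
        dead = False
        while remaining:
            if perm:
                prev = perm[-1]
                options = [
                    i for i, c in enumerate(remaining)
                    if c[0] != prev[0] and c[1] != prev[1]
                ]
            else:
                options = list(range(len(remaining)))
            if not options:
                dead = True
                break
            perm.append(remaining.pop(options[rng.integers(len(options))]))
        if not dead and len(perm) == n:
            return perm
    raise ValueError(
        f"could not find a block order without consecutive repeats in {max_tries} tries"
    )


def condition_regressors(
    design: BlockDesign, run: int, n_scans: int | None = None
) -> pd.DataFrame:
    """HRF-convolved boxcar regressor per (condition, stimulus type) cell for
    one run; columns are sorted condition keys, index is scan number."""
    if n_scans is None:
        n_scans = design.n_scans_per_run
    tr = design.tr
    keys = design.condition_keys
    hrf = canonical_hrf(tr)
    out = np.zeros((n_scans, len(keys)))
    t = np.arange(n_scans) * tr
    for b in design.runs[run]:
        k = keys.index(condition_key(b.condition_label, b.stimulus_type))
        box = ((t >= b.onset_s) & (t < b.onset_s + b.duration_s)).astype(float)
        out[:, k] += box
    for k in range(len(keys)):
        out[:, k] = np.convolve(out[:, k], hrf)[:n_scans]
    return pd.DataFrame(out, columns=keys)


# ---------------------------------------------------------------------------
# Effect and noise specifications
# ---------------------------------------------------------------------------

Edge = tuple[int, int]


@dataclass
class EffectSpec:
    """Ground-truth connectivity structure.

    ``base_covariance`` is the resting ROI covariance (unit diagonal, so
    off-diagonal entries are correlations). ``condition_deltas`` maps an
    emotion label to a list of ``((i, j), delta_r)`` increments applied to the
    covariance while that emotion's blocks drive the signal; these are the
    edges a recovery analysis should find. ``activation_amplitudes`` maps an
    emotion label to a per-ROI gain of the HRF-convolved activation term.
    """

    n_rois: int
    base_covariance: np.ndarray
    condition_deltas: dict[str, list[tuple[Edge, float]]] = field(default_factory=dict)
    activation_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        if self.base_covariance.shape != (self.n_rois, self.n_rois):
            raise ValueError("base_covariance shape mismatch")
        if not np.allclose(self.base_covariance, self.base_covariance.T, atol=1e-10):
            raise ValueError("base_covariance must be symmetric")
        if np.linalg.eigvalsh(self.base_covariance).min() <= 1e-10:
            raise ValueError("base_covariance must be positive-definite")
        for cond, edges in self.condition_deltas.items():
            for (i, j), _ in edges:
                if not (0 <= j < i < self.n_rois):
                    raise ValueError(
                        f"condition {cond!r}: delta edge ({i},{j}) must satisfy "
                        f"0 <= j < i < n_rois"
                    )
            cov = self.condition_covariance(cond)
            if np.linalg.eigvalsh(cov).min() <= 1e-10:
                raise ValueError(
                    f"perturbed covariance for condition {cond!r} is not "
                    "positive-definite"
                )

    def condition_covariance(self, condition_label: str) -> np.ndarray:
        cov = self.base_covariance.copy()
        for (i, j), d in self.condition_deltas.get(condition_label, []):
            cov[i, j] += d
            cov[j, i] += d
        return cov


@dataclass(frozen=True)
class NoiseSpec:
    """Confound magnitudes. Motion random-walk steps are scaled so that the
    mean absolute displacement over a ~300-scan run is of order 0.1-0.3 mm /
    degrees, matching typical compliant-adult head motion."""

    thermal_sd: float = 0.5
    motion_walk_sd: float = 0.015
    motion_coupling_sd: float = 0.4
    drift_slope_range: tuple[float, float] = (-0.8, 0.8)
    n_nuisance_components: int = 10
    nuisance_loading_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("thermal_sd", "motion_walk_sd", "motion_coupling_sd",
                     "nuisance_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SubjectData:
    """Per-run ROI time series (scans x n_rois) and confound regressors."""

    subject_id: str
    timeseries: list[np.ndarray]
    confounds: list[pd.DataFrame]

    def validate(self, design: BlockDesign | None = None) -> None:
        if len(self.timeseries) != len(self.confounds):
            raise ValueError("runs mismatch between timeseries and confounds")
        for r, (ts, cf) in enumerate(zip(self.timeseries, self.confounds)):
            if not np.all(np.isfinite(ts)):
                raise ValueError(f"{self.subject_id} run {r}: non-finite values")
            if len(cf.columns) != len(set(cf.columns)):
                raise ValueError(f"{self.subject_id} run {r}: duplicate confound names")
            if ts.shape[0] != len(cf):
                raise ValueError(f"{self.subject_id} run {r}: scan count mismatch")
            if design is not None and ts.shape[0] != design.n_scans_per_run:
                raise ValueError(
                    f"{self.subject_id} run {r}: {ts.shape[0]} scans, design "
                    f"expects {design.n_scans_per_run}"
                )

    @property
    def n_runs(self) -> int:
        return len(self.timeseries)


def blocked_correlation(n_rois: int, n_blocks: int = 4, rho: float = 0.5) -> np.ndarray:
    """Block-structured correlation matrix: ROIs partitioned into ``n_blocks``
    communities with within-community correlation ``rho``. Positive-definite
    for 0 <= rho < 1 and gives every community member positive edges, so the
    positive-FC selection step has non-trivial work under the null."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    cov = np.eye(n_rois)
    bounds = np.linspace(0, n_rois, n_blocks + 1).astype(int)
    for a, b in zip(bounds, bounds[1:]):
        cov[a:b, a:b] = rho
    np.fill_diagonal(cov, 1.0)
    return cov


def disjoint_edges(n_edges: int, n_rois: int, offset: int = 0) -> list[Edge]:
    """``n_edges`` node-disjoint edges (2k+1+offset, 2k+offset): adding a common
    correlation increment to disjoint edges of a block correlation keeps it
    positive-definite for moderate increments."""
    if 2 * n_edges + offset > n_rois:
        raise ValueError("not enough ROIs for that many disjoint edges")
    return [(offset + 2 * k + 1, offset + 2 * k) for k in range(n_edges)]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
_REGRESSOR_TAU = 1e-6


def simulate_subject(
    design: BlockDesign,
    effect: EffectSpec,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sub-01",
) -> SubjectData:
    """One subject's multi-run ROI BOLD.

    Scan-wise covariance switching: a scan belongs to the condition whose
    HRF-convolved regressor is maximal at that scan (and above a small
    threshold); its ROI vector is drawn from that emotion's perturbed
    covariance, rest scans from the base covariance. Activation, motion
    artifact, drift, nuisance components and thermal noise are added on top;
    the motion and nuisance traces are returned as the confound matrix.
    """
    rng = np.random.default_rng(seed)
    n_rois = effect.n_rois
    keys = design.condition_keys
    labels_of_key = {k: k.split("|", 1)[0] for k in keys}

    chols: dict[str, np.ndarray] = {"__rest__": np.linalg.cholesky(effect.base_covariance)}
    for lab in {labels_of_key[k] for k in keys}:
        chols[lab] = np.linalg.cholesky(effect.condition_covariance(lab))

    ts_runs, cf_runs = [], []
    for r in range(design.n_runs):
        n_scans = design.n_scans_per_run
        regs = condition_regressors(design, r).to_numpy()
        state = np.full(n_scans, -1)
        peak = regs.max(axis=1)
        active = peak > _REGRESSOR_TAU
        state[active] = regs[active].argmax(axis=1)

        z = rng.standard_normal((n_scans, n_rois))
        y = np.empty_like(z)
        rest = state == -1
        y[rest] = z[rest] @ chols["__rest__"].T
        for k, key in enumerate(keys):
            sel = state == k
            if sel.any():
                y[sel] = z[sel] @ chols[labels_of_key[key]].T

        # HRF-convolved activation per emotion (summed over stimulus types)
        for lab, amp in effect.activation_amplitudes.items():
            amp = np.asarray(amp, dtype=float)
            cols = [i for i, key in enumerate(keys) if labels_of_key[key] == lab]
            if cols:
                y += regs[:, cols].sum(axis=1)[:, None] * amp[None, :]

        motion = np.cumsum(
            rng.standard_normal((n_scans, 6)) * noise.motion_walk_sd, axis=0
        )
        y += motion @ (rng.standard_normal((6, n_rois)) * noise.motion_coupling_sd)

        lo, hi = noise.drift_slope_range
        slopes = rng.uniform(lo, hi, size=n_rois)
        y += np.linspace(0.0, 1.0, n_scans)[:, None] * slopes[None, :]

        m = noise.n_nuisance_components
        if m > 0:
            comps = _smooth_noise(rng, n_scans, m)
            y += comps @ (rng.standard_normal((m, n_rois)) * noise.nuisance_loading_sd)
        else:
            comps = np.zeros((n_scans, 0))

        y += rng.standard_normal((n_scans, n_rois)) * noise.thermal_sd

        cf = pd.DataFrame(
            np.hstack([motion, comps]),
            columns=_MOTION_COLS + [f"comp_cor_{i:02d}" for i in range(m)],
        )
        ts_runs.append(y)
        cf_runs.append(cf)

    out = SubjectData(subject_id=subject_id, timeseries=ts_runs, confounds=cf_runs)
    out.validate(design)
    return out


def _smooth_noise(rng, n_scans, m, width=5):
    """Low-frequency-ish shared components: boxcar-smoothed unit-variance noise."""
    x = rng.standard_normal((n_scans + width - 1, m))
    kernel = np.ones(width) / width
    out = np.empty((n_scans, m))
    for c in range(m):
        out[:, c] = np.convolve(x[:, c], kernel, mode="valid")
    sd = out.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_cohort(
    n_subjects: int,
    design: BlockDesign,
    effect: EffectSpec,
    noise: NoiseSpec,
    seed: int,
) -> list[SubjectData]:
    """Independent subjects from per-subject seeds spawned off ``seed``."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for leave-one-out analyses")
    child_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        simulate_subject(design, effect, noise, s, subject_id=f"sub-{i + 1:02d}")
        for i, s in enumerate(child_seeds)
    ]


def write_dataset(
    outdir: str | Path,
    cohort: Sequence[SubjectData],
    design: BlockDesign,
    effect: EffectSpec | None = None,
) -> None:
    """TSV-per-run dataset layout: ``sub-XX_run-K_bold.tsv`` (scans x ROIs,
    header = node ids), ``sub-XX_run-K_confounds.tsv``, ``design.json`` and,
    when an effect spec is given, ``ground_truth.json`` with injected edges."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_rois = cohort[0].timeseries[0].shape[1]
    node_cols = [f"n{i + 1:03d}" for i in range(n_rois)]
    for sub in cohort:
        for r, (ts, cf) in enumerate(zip(sub.timeseries, sub.confounds)):
            stem = f"{sub.subject_id}_run-{r + 1}"
            pd.DataFrame(ts, columns=node_cols).to_csv(
                outdir / f"{stem}_bold.tsv", sep="\t", index=False
            )
            cf.to_csv(outdir / f"{stem}_confounds.tsv", sep="\t", index=False)
    (outdir / "design.json").write_text(json.dumps(design.to_dict(), indent=1))
    if effect is not None:
        gt = {
            cond: [[list(e), d] for e, d in edges]
            for cond, edges in effect.condition_deltas.items()
        }
        (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
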