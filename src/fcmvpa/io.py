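"""File I/O: atlas node tables, TSV datasets, and run configuration.

All interchange formats are plain text: TSV for time series, confounds,
atlas tables and edge lists; JSON for designs, ground truth and result
summaries; YAML or JSON for run configuration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .networks import MODULES
from .synthetic import BlockDesign, SubjectData

__all__ = [
    "ATLAS_COLUMNS",
    "read_atlas",
    "write_atlas",
    "synthetic_atlas",
    "read_dataset",
    "RunConfig",
    "load_config",
]

ATLAS_COLUMNS = ["node_id", "label", "mni_x", "mni_y", "mni_z", "module", "hemisphere"]


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Validated atlas node table.

    Required TSV columns: node_id (1-based, contiguous), label, mni_x/y/z in
    mm, module (one of the 7-category vocabulary, case-insensitive),
    hemisphere (L/R). Errors carry the offending row number.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"atlas missing columns: {missing}")
    dup = df["node_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate node_id at row {int(dup.idxmax()) + 2}")
    ids = df["node_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(1, len(df) + 1)):
        raise ValueError("node_id must be contiguous 1..N")
    df = df.sort_values("node_id").reset_index(drop=True)
    df["module"] = df["module"].astype(str).str.strip().str.lower()
    bad = ~df["module"].isin(MODULES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown module {df['module'].iloc[row]!r} at row {row + 2}; "
            f"expected one of {MODULES}"
        )
    df["hemisphere"] = df["hemisphere"].astype(str).str.strip().str.upper()
    bad = ~df["hemisphere"].isin(["L", "R"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"hemisphere must be L or R at row {row + 2}")
    return df


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas[ATLAS_COLUMNS].to_csv(path, sep="\t", index=False)


def synthetic_atlas(n_rois: int = 246, seed: int = 0) -> pd.DataFrame:
    """SYNTHETIC stand-in for a real 246-node parcellation table.

    Placeholder coordinates and plausible module proportions only — node
    labels, positions and module assignments carry no anatomical meaning.
    Users analysing real data must supply their parcellation's node table.
    """
    rng = np.random.default_rng(seed)
    # rough cortical/subcortical proportions of a whole-brain parcellation
    props = {
        "frontal": 0.28,
        "temporal": 0.20,
        "parietal": 0.16,
        "occipital": 0.12,
        "limbic": 0.08,
        "insula": 0.04,
        "subcortical": 0.12,
    }
    counts = {m: int(round(p * n_rois)) for m, p in props.items()}
    drift = n_rois - sum(counts.values())
    counts["frontal"] += drift
    modules = [m for m, c in counts.items() for _ in range(c)]
    rows = []
    for i, m in enumerate(modules):
        hemi = "L" if i % 2 == 0 else "R"
        x = rng.uniform(5, 65) * (-1 if hemi == "L" else 1)
        rows.append(
            {
                "node_id": i + 1,
                "label": f"{m.capitalize()}_{i // 2 + 1}_{hemi}",
                "mni_x": round(float(x), 1),
                "mni_y": round(float(rng.uniform(-90, 60)), 1),
                "mni_z": round(float(rng.uniform(-40, 70)), 1),
                "module": m,
                "hemisphere": hemi,
            }
        )
    return pd.DataFrame(rows)


def read_dataset(directory: str | Path) -> tuple[list[SubjectData], BlockDesign]:
    """Load a dataset written by :func:`fcmvpa.synthetic.write_dataset`.

    Returns subjects sorted by id, with scan counts validated against the
    design.
    """
    directory = Path(directory)
    design = BlockDesign.from_dict(
        json.loads((directory / "design.json").read_text())
    )
    bold = sorted(directory.glob("sub-*_bold.tsv"))
    if not bold:
        raise FileNotFoundError(f"no sub-*_bold.tsv files in {directory}")
    by_sub: dict[str, dict[int, Path]] = {}
    for p in bold:
        m = re.match(r"(sub-.+)_run-(\d+)_bold\.tsv$", p.name)
        if not m:
            raise ValueError(f"unexpected file name {p.name}")
        by_sub.setdefault(m.group(1), {})[int(m.group(2))] = p
    cohort = []
    for sub_id in sorted(by_sub):
        runs = by_sub[sub_id]
        ts_list, cf_list = [], []
        for r in sorted(runs):
            ts = pd.read_csv(runs[r], sep="\t").to_numpy(dtype=float)
            if ts.shape[0] != design.n_scans_per_run:
                raise ValueError(
                    f"{runs[r].name}: {ts.shape[0]} scans, design expects "
                    f"{design.n_scans_per_run}"
                )
            cf_path = directory / f"{sub_id}_run-{r}_confounds.tsv"
            if not cf_path.exists():
                raise FileNotFoundError(f"expected confound file {cf_path.name}")
            cf_list.append(pd.read_csv(cf_path, sep="\t"))
            ts_list.append(ts)
        sub = SubjectData(subject_id=sub_id, timeseries=ts_list, confounds=cf_list)
        sub.validate(design)
        cohort.append(sub)
    return cohort, design


@dataclass
class RunConfig:
    """End-to-end run parameters; ``seed`` governs every stochastic stage."""

    seed: int
    output_dir: str = "fcmvpa_out"
    dataset_dir: str | None = None
    atlas_path: str | None = None
    # synthetic cohort (used when dataset_dir is None)
    n_subjects: int = 20
    n_rois: int = 60
    n_runs: int = 2
    conditions: tuple[str, ...] = ("anger", "fear", "joy")
    stimulus_types: tuple[str, ...] = ("face", "body")
    repetitions: int = 2
    # denoising
    low_hz: float = 0.01
    high_hz: float = 0.1
    # decoding
    decode_stimulus_type: str = "face"
    selection_method: str = "positive_fdr"
    q: float = 0.01
    k: int | None = None
    cost: float = 1.0
    # inference
    n_perm: int = 99
    perm_rule: str = "add_one"
    # networks
    network_k: int = 50

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("conditions", "stimulus_types"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        out = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            out[f] = list(v) if isinstance(v, tuple) else v
        return out


def load_config(path: str | Path) -> RunConfig:
    """RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.from_dict(data)
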