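"""HDF5 and CSV layouts for epoched datasets and derived matrices.

Dataset layout: one HDF5 group per participant, one subgroup per condition
(label ``attention-cue-motion``), holding a ``trials`` dataset of shape
(n_trials, n_rois, n_samples) with a ``t0_s`` attribute. File-level
attributes: ``sampling_rate_hz``, ``roi_labels``, ``roi_hemispheres`` and
``seed``. The same layout is accepted for real exported data. Parcellations
round-trip through a two-column text file (label, hemisphere).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    Condition,
    ConditionConnectivity,
    EpochedRoiSeries,
    HubResult,
    Parcellation,
    SyntheticDataset,
)

__all__ = [
    "write_dataset_h5",
    "read_dataset_h5",
    "write_parcellation_txt",
    "read_parcellation_txt",
    "write_block_csv",
    "read_block_csv",
    "write_connectivity_csv",
    "read_connectivity_csv",
    "write_hub_json",
    "ndte_long_format",
]


def write_dataset_h5(dataset: SyntheticDataset, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = dataset.sampling_rate
        f.attrs["roi_labels"] = list(dataset.parcellation.labels)
        f.attrs["roi_hemispheres"] = list(dataset.parcellation.hemispheres)
        f.attrs["seed"] = dataset.seed
        for (pid, cond), block in sorted(dataset.blocks.items()):
            grp = f.require_group(f"{pid}/{cond.label()}")
            ds = grp.create_dataset("trials", data=block.values)
            ds.attrs["t0_s"] = block.t0
    return path


def read_dataset_h5(path: str | Path) -> SyntheticDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    with h5py.File(path, "r") as f:
        for attr in ("sampling_rate_hz", "roi_labels", "roi_hemispheres"):
            if attr not in f.attrs:
                raise ValueError(f"malformed dataset file: missing attribute {attr!r}")
        fs = float(f.attrs["sampling_rate_hz"])
        parc = Parcellation(
            labels=tuple(str(s) for s in f.attrs["roi_labels"]),
            hemispheres=tuple(str(s) for s in f.attrs["roi_hemispheres"]),
        )
        seed = int(f.attrs.get("seed", 0))
        blocks: dict[tuple[str, Condition], EpochedRoiSeries] = {}
        for pid in f:
            for cond_label in f[pid]:
                grp = f[pid][cond_label]
                if "trials" not in grp:
                    raise ValueError(
                        f"malformed dataset file: group {pid}/{cond_label} has no 'trials'"
                    )
                values = np.asarray(grp["trials"])
                if values.size == 0:
                    raise ValueError(f"empty trial group {pid}/{cond_label}")
                cond = Condition.from_label(cond_label)
                blocks[(pid, cond)] = EpochedRoiSeries(
                    values=values,
                    sampling_rate=fs,
                    t0=float(grp["trials"].attrs.get("t0_s", 0.0)),
                    parcellation=parc,
                    condition=cond,
                    participant_id=pid,
                )
    if not blocks:
        raise ValueError(f"dataset file {path} contains no blocks")
    return SyntheticDataset(
        blocks=blocks, truth={}, parcellation=parc, sampling_rate=fs, seed=seed
    )


def write_parcellation_txt(parc: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for label, hemi in zip(parc.labels, parc.hemispheres):
            fh.write(f"{label}\t{hemi}\n")
    return path


def read_parcellation_txt(path: str | Path) -> Parcellation:
    labels, hemis = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed parcellation line: {line!r}")
            labels.append(parts[0])
            hemis.append(parts[1])
    return Parcellation(labels=tuple(labels), hemispheres=tuple(hemis))


def write_block_csv(block: EpochedRoiSeries, path: str | Path) -> Path:
    """Long-format CSV of one epoched block (trial, roi, sample, value)."""
    path = Path(path)
    n_trials, n_rois, n_time = block.values.shape
    trial, roi, sample = np.meshgrid(
        np.arange(n_trials), np.arange(n_rois), np.arange(n_time), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "trial": trial.ravel(),
            "roi": [block.parcellation.labels[i] for i in roi.ravel()],
            "sample": sample.ravel(),
            "value": block.values.ravel(),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_block_csv(
    path: str | Path,
    parcellation: Parcellation,
    sampling_rate: float,
    t0: float = 0.0,
) -> EpochedRoiSeries:
    df = pd.read_csv(path)
    required = {"trial", "roi", "sample", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"malformed block CSV: missing column(s) {sorted(missing)}")
    labels = list(parcellation.labels)
    unknown = set(df["roi"].unique()) - set(labels)
    if unknown:
        raise ValueError(f"ROI labels not in parcellation: {sorted(unknown)}")
    n_trials = int(df["trial"].max()) + 1
    n_time = int(df["sample"].max()) + 1
    values = np.zeros((n_trials, len(labels), n_time))
    roi_idx = df["roi"].map({lbl: i for i, lbl in enumerate(labels)}).to_numpy()
    values[df["trial"].to_numpy(), roi_idx, df["sample"].to_numpy()] = df["value"].to_numpy()
    return EpochedRoiSeries(
        values=values, sampling_rate=sampling_rate, t0=t0, parcellation=parcellation
    )


def write_connectivity_csv(
    conn: ConditionConnectivity, parc: Parcellation, path: str | Path
) -> Path:
    """C_All as a labelled square CSV (rows = targets/inflow, cols = sources)."""
    path = Path(path)
    df = pd.DataFrame(conn.c_all, index=parc.labels, columns=parc.labels)
    df.to_csv(path)
    return path


def read_connectivity_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def write_hub_json(result: HubResult, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "mode": result.mode,
        "alpha": result.alpha,
        "members": result.members,
        "labels": result.labels,
        "g_hub": result.g_hub,
        "p": result.p,
        "final_set": result.final_set,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def ndte_long_format(
    f: np.ndarray, parc: Parcellation, trial: int | None = None
) -> pd.DataFrame:
    """Long-format (source, target, trial, F) table of one NDTE matrix."""
    n = f.shape[0]
    ti, si = np.nonzero(~np.eye(n, dtype=bool))
    return pd.DataFrame(
        {
            "source": [parc.labels[j] for j in si],
            "target": [parc.labels[i] for i in ti],
            "trial": trial,
            "F": f[ti, si],
        }
    )
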