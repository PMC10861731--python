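"""Plain-text and HDF5 containers for cohort artifacts.

Rosters and covariates travel as CSV, adjacency as a two-column TSV of
region labels, parameter tables as tidy TSV, per-subject signals as HDF5
(datasets ``/data`` (R x T), ``/fs``, ``/regions``) with a CSV fallback.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._exceptions import SchemaError
from .conditioning import RegionTimeSeries
from .stats import RegionAdjacency

__all__ = [
    "write_roster",
    "read_roster",
    "write_adjacency",
    "read_adjacency",
    "write_timeseries",
    "read_timeseries",
    "write_params_table",
    "read_params_table",
    "write_ground_truth",
]

ROSTER_COLUMNS = (
    "id", "age", "diagnosis", "mmse", "fab",
    "severity", "extent", "ratio", "meg_artifact_severe",
)


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.to_csv(path, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    roster = pd.read_csv(path)
    missing = [c for c in ("id", "diagnosis") if c not in roster.columns]
    if missing:
        raise SchemaError(f"roster lacks required columns {missing}")
    return roster


def write_adjacency(adjacency: RegionAdjacency, path: str | Path) -> None:
    rows = [
        (adjacency.labels[i], adjacency.labels[j]) for i, j in adjacency.edges
    ]
    pd.DataFrame(rows, columns=["region_a", "region_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_adjacency(path: str | Path, labels: list[str] | None = None) -> RegionAdjacency:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise SchemaError("adjacency TSV needs two label columns")
    pairs = list(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
    if labels is None:
        labels = sorted({lab for pair in pairs for lab in pair})
    return RegionAdjacency.from_edge_labels(labels, pairs)


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=ts.data)
        fh.create_dataset("fs", data=float(ts.fs))
        fh.create_dataset(
            "regions", data=np.array(ts.region_labels, dtype=h5py.string_dtype())
        )
        fh.attrs["subject_id"] = ts.subject_id


def read_timeseries(path: str | Path) -> RegionTimeSeries:
    with h5py.File(path, "r") as fh:
        return RegionTimeSeries(
            subject_id=str(fh.attrs.get("subject_id", Path(path).stem)),
            fs=float(fh["fs"][()]),
            region_labels=[s.decode() if isinstance(s, bytes) else str(s) for s in fh["regions"][()]],
            data=np.asarray(fh["data"][()]),
        )


def write_params_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True)


def read_params_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_ground_truth(truth, path: str | Path) -> None:
    """Persist the scalar ground truth (latent, covariates, planted signs).

    Target spectra are regenerable from the configuration and are not
    serialized.
    """
    payload = {
        "latent": np.asarray(truth.latent).tolist(),
        "subject_ids": list(truth.subject_ids),
        "region_labels": list(truth.region_labels),
        "planted_signs": {f"{p}|{c}": s for (p, c), s in truth.planted_signs.items()},
        "covariates": truth.covariates.reset_index().to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
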