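"""Reading and writing per-cell time-series datasets.

Two on-disk layouts are supported:

``csv_long``
    A directory containing ``cells.csv`` (long format, one row per cell per
    frame) and ``adjacency.csv`` (directed edge list that must be symmetric,
    optionally per-frame).
``json``
    A single JSON document bundling cell tables and adjacency.

Missing observations are written/read as empty fields (NaN in memory) and are
never zero-filled.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CellTrack,
    EmbryoDataset,
    SchemaError,
    ValidationError,
)

CELL_COLUMNS = [
    "embryo_id", "cell_id", "frame", "time_s", "myosin", "area_um2",
    "centroid_x", "centroid_y", "is_boundary",
]
ADJ_COLUMNS = ["cell_a", "cell_b"]
TRACK_COLUMNS = ["track_id", "cell_id", "first_frame", "last_frame"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def load_dataset(
    path: str | Path,
    format: str = "csv_long",
    genotype: str | None = None,
) -> EmbryoDataset:
    """Load and validate one embryo's dataset.

    Parameters
    ----------
    path
        For ``csv_long``: a directory holding ``cells.csv`` and
        ``adjacency.csv``. For ``json``: a single bundle file.
    genotype
        Overrides the genotype recorded in the file (if any).

    Returns
    -------
    EmbryoDataset
        Fully validated; missing observations preserved as NaN.
    """
    path = Path(path)
    if format == "csv_long":
        cells_df = pd.read_csv(path / "cells.csv")
        adj_path = path / "adjacency.csv"
        adj_df = pd.read_csv(adj_path) if adj_path.exists() else None
        meta: dict = {}
    elif format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        cells_df = pd.DataFrame(doc["cells"])
        adj_df = pd.DataFrame(doc["adjacency"]) if doc.get("adjacency") else None
        meta = doc.get("meta", {})
    else:
        raise ValueError(f"unknown format {format!r}")

    _require_columns(cells_df, CELL_COLUMNS, "cell table")
    if adj_df is not None and len(adj_df):
        _require_columns(adj_df, ADJ_COLUMNS, "adjacency table")

    dataset = _build_dataset(cells_df, adj_df, meta, genotype)
    dataset.validate()
    return dataset


def _build_dataset(cells_df, adj_df, meta, genotype) -> EmbryoDataset:
    embryo_ids = cells_df["embryo_id"].unique()
    if len(embryo_ids) != 1:
        raise ValidationError(
            f"expected a single embryo per dataset, found {sorted(map(str, embryo_ids))}"
        )
    embryo_id = str(embryo_ids[0])

    static_adj: dict[str, list] = {}
    per_frame_adj: dict[str, dict[int, list]] = {}
    if adj_df is not None and len(adj_df):
        adj_df = adj_df.astype({"cell_a": str, "cell_b": str})
        if "frame" in adj_df.columns and adj_df["frame"].notna().any():
            for (a, f), grp in adj_df.groupby(["cell_a", "frame"]):
                per_frame_adj.setdefault(a, {})[int(f)] = sorted(grp["cell_b"])
        else:
            for a, grp in adj_df.groupby("cell_a"):
                static_adj[a] = sorted(grp["cell_b"])

    cells: dict[str, CellTrack] = {}
    for cell_id, grp in cells_df.groupby("cell_id", sort=True):
        cell_id = str(cell_id)
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if cell_id in per_frame_adj:
            by_frame = per_frame_adj[cell_id]
            neighbors: list = [by_frame.get(int(f), []) for f in frames]
        else:
            neighbors = static_adj.get(cell_id, [])
        cells[cell_id] = CellTrack(
            cell_id=cell_id,
            embryo_id=str(grp["embryo_id"].iloc[0]),
            times=grp["time_s"].to_numpy(dtype=float),
            myosin=grp["myosin"].to_numpy(dtype=float),
            area=grp["area_um2"].to_numpy(dtype=float),
            centroid=grp[["centroid_x", "centroid_y"]].to_numpy(dtype=float),
            neighbors=neighbors,
            is_boundary=bool(grp["is_boundary"].iloc[0]),
        )

    n_missing = sum(c.n_missing() for c in cells.values())
    dataset = EmbryoDataset(
        embryo_id=embryo_id,
        cells=cells,
        genotype=genotype or meta.get("genotype", "other"),
        frame_interval=meta.get("frame_interval"),
        alignment_offset=float(meta.get("alignment_offset", 0.0)),
    )
    dataset.n_missing = n_missing  # type: ignore[attr-defined]
    return dataset


def dataset_to_frames(dataset: EmbryoDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format cell table and symmetric adjacency edge list."""
    rows = []
    for track in dataset.cells.values():
        for i in range(track.n_frames):
            rows.append(
                {
                    "embryo_id": track.embryo_id,
                    "cell_id": track.cell_id,
                    "frame": i,
                    "time_s": track.times[i],
                    "myosin": track.myosin[i],
                    "area_um2": track.area[i],
                    "centroid_x": track.centroid[i, 0],
                    "centroid_y": track.centroid[i, 1],
                    "is_boundary": track.is_boundary,
                }
            )
    cells_df = pd.DataFrame(rows, columns=CELL_COLUMNS)

    adj_rows = []
    for track in dataset.cells.values():
        if track.has_per_frame_neighbors:
            for f, lst in enumerate(track.neighbors):
                for nb in lst:
                    adj_rows.append({"cell_a": track.cell_id, "cell_b": nb, "frame": f})
        else:
            for nb in track.neighbors:
                adj_rows.append({"cell_a": track.cell_id, "cell_b": nb})
    adj_df = pd.DataFrame(adj_rows, columns=ADJ_COLUMNS + (["frame"] if adj_rows and "frame" in adj_rows[0] else []))
    return cells_df, adj_df


def save_dataset(dataset: EmbryoDataset, path: str | Path, format: str = "csv_long") -> None:
    """Inverse of :func:`load_dataset` (round-trip identity, incl. missingness)."""
    path = Path(path)
    cells_df, adj_df = dataset_to_frames(dataset)
    meta = {
        "genotype": dataset.genotype,
        "frame_interval": dataset.frame_interval,
        "alignment_offset": dataset.alignment_offset,
    }
    if format == "csv_long":
        path.mkdir(parents=True, exist_ok=True)
        cells_df.to_csv(path / "cells.csv", index=False)
        adj_df.to_csv(path / "adjacency.csv", index=False)
    elif format == "json":
        doc = {
            "meta": meta,
            "cells": _frame_to_jsonable(cells_df),
            "adjacency": _frame_to_jsonable(adj_df),
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def _frame_to_jsonable(df: pd.DataFrame) -> dict:
    out = {}
    for col in df.columns:
        vals = df[col]
        if vals.dtype.kind == "f":
            out[col] = [None if np.isnan(v) else float(v) for v in vals]
        else:
            out[col] = vals.tolist()
    return out


def load_manual_tracks(path: str | Path) -> pd.DataFrame:
    """Manual pulse-track table: track_id, cell_id, first_frame, last_frame."""
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, "manual track table")
    df = df.astype({"track_id": str, "cell_id": str, "first_frame": int, "last_frame": int})
    return df


def standard_frame_interval(datasets) -> float:
    """Average frame interval across a dataset collection.

    Used as the common resampling rate for pulse-centric windows.
    """
    intervals = [float(d.frame_interval) for d in datasets]
    return float(np.mean(intervals))
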