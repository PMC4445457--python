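"""Core domain types for per-cell contraction time series.

The central containers are :class:`CellTrack` (one cell's myosin/area/centroid
time series plus its neighbour lists) and :class:`EmbryoDataset` (all tracked
cells of one embryo with the cell adjacency and the temporal-alignment offset).
Detected contractile events are represented by :class:`Pulse`.

Missing observations are stored as NaN and are never imputed at this level;
gap handling is a pulse-windowing concern (see :mod:`pulsecraft.features`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd

GENOTYPES = ("wild_type", "twi_RNAi", "control_injected", "other")
CLASS_LABELS = ("ratcheted", "unratcheted", "unconstricting")
CURATION_CATEGORIES = (
    "one_to_one",
    "missed_by_fitting",
    "added_by_fitting",
    "split_by_fitting",
    "merged_by_fitting",
    "unreviewed",
)


class SchemaError(ValueError):
    """A required column or field is absent from an input table."""


class ValidationError(ValueError):
    """Input data violate a structural invariant (ordering, symmetry, ...)."""


class AlignmentError(RuntimeError):
    """Temporal alignment could not be determined from the mean-area trace."""


@dataclass
class CellTrack:
    """Time series of a single tracked cell.

    Parameters
    ----------
    cell_id, embryo_id
        Identifiers; neighbour lists refer to ``cell_id`` values.
    times
        Observation times in seconds, strictly increasing.
    myosin
        Apical myosin intensity (arbitrary units); NaN marks missing frames.
    area
        Apical area in μm²; NaN marks missing frames.
    centroid
        ``(n_frames, 2)`` centroid coordinates in μm.
    neighbors
        Either one static list of neighbour cell ids, or one list per frame.
    is_boundary
        True for cells on the edge of the segmented tissue.
    """

    cell_id: str
    embryo_id: str
    times: np.ndarray
    myosin: np.ndarray
    area: np.ndarray
    centroid: np.ndarray
    neighbors: Sequence = field(default_factory=list)
    is_boundary: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.myosin = np.asarray(self.myosin, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def has_per_frame_neighbors(self) -> bool:
        return bool(self.neighbors) and isinstance(self.neighbors[0], (list, tuple))

    def neighbors_at(self, frame: int) -> list:
        """Neighbour ids at a frame (per-frame list if present, else static)."""
        if self.has_per_frame_neighbors:
            frame = min(max(frame, 0), len(self.neighbors) - 1)
            return list(self.neighbors[frame])
        return list(self.neighbors)

    def frame_of_time(self, t: float) -> int:
        """Index of the observation nearest to time ``t``."""
        return int(np.argmin(np.abs(self.times - t)))

    def n_missing(self) -> int:
        return int(np.isnan(self.myosin).sum() + np.isnan(self.area).sum())

    def validate(self) -> None:
        n = self.n_frames
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"cell {self.cell_id}: times are not strictly increasing"
            )
        for name in ("myosin", "area"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"cell {self.cell_id}: {name} length != times length"
                )
        if self.centroid.shape != (n, 2):
            raise ValidationError(f"cell {self.cell_id}: centroid must be (n, 2)")
        obs = self.myosin[~np.isnan(self.myosin)]
        if np.any(obs < 0):
            raise ValidationError(f"cell {self.cell_id}: negative myosin intensity")
        if self.has_per_frame_neighbors and len(self.neighbors) != n:
            raise ValidationError(
                f"cell {self.cell_id}: per-frame neighbour list length != n_frames"
            )


@dataclass
class EmbryoDataset:
    """All tracked cells of one embryo plus adjacency and alignment state."""

    embryo_id: str
    cells: dict[str, CellTrack]
    genotype: str = "other"
    frame_interval: float | None = None
    alignment_offset: float = 0.0
    external_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.frame_interval is None and self.cells:
            track = next(iter(self.cells.values()))
            if track.n_frames > 1:
                self.frame_interval = float(np.median(np.diff(track.times)))

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterable[CellTrack]:
        return iter(self.cells.values())

    def validate(self) -> None:
        for track in self.cells.values():
            track.validate()
        bad_pairs = self._asymmetric_pairs()
        if bad_pairs:
            raise ValidationError(
                "asymmetric adjacency, offending pairs: "
                + ", ".join(f"({a}, {b})" for a, b in bad_pairs)
            )
        for track in self.cells.values():
            lists = track.neighbors if track.has_per_frame_neighbors else [track.neighbors]
            for lst in lists:
                for nb in lst:
                    if nb not in self.cells and nb not in self.external_ids:
                        raise ValidationError(
                            f"cell {track.cell_id}: neighbour {nb!r} does not "
                            "resolve to a cell and is not flagged external"
                        )

    def _asymmetric_pairs(self) -> list[tuple[str, str]]:
        bad = []
        for track in self.cells.values():
            for nb in set(self._static_neighbors(track)):
                other = self.cells.get(nb)
                if other is None:
                    continue
                if track.cell_id not in set(self._static_neighbors(other)):
                    bad.append((track.cell_id, nb))
        return sorted(bad)

    @staticmethod
    def _static_neighbors(track: CellTrack) -> list:
        if track.has_per_frame_neighbors:
            out: set = set()
            for lst in track.neighbors:
                out.update(lst)
            return sorted(out)
        return list(track.neighbors)

    def adjacency(self) -> nx.Graph:
        """Static neighbour graph (union over frames for per-frame lists)."""
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for track in self.cells.values():
            for nb in self._static_neighbors(track):
                if nb in self.cells:
                    g.add_edge(track.cell_id, nb)
        return g

    def common_times(self) -> np.ndarray:
        """Shared time base; raises if cells are on different grids."""
        ref = next(iter(self.cells.values())).times
        for track in self.cells.values():
            if track.n_frames != len(ref) or not np.allclose(track.times, ref):
                raise ValidationError(
                    "cells do not share a common time base; align/resample first"
                )
        return ref

    def mean_area(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean apical area over cells per frame (NaN-aware) on the shared grid."""
        times = self.common_times()
        stack = np.vstack([c.area for c in self.cells.values()])
        with np.errstate(invalid="ignore"):
            return times, np.nanmean(stack, axis=0)

    def apply_alignment(self, offset: float | None = None) -> "EmbryoDataset":
        """Return a copy with all times shifted so that t = 0 is the offset."""
        if offset is None:
            offset = self.alignment_offset
        cells = {
            cid: replace(c, times=c.times - offset) for cid, c in self.cells.items()
        }
        return replace(self, cells=cells, alignment_offset=0.0)


@dataclass
class Pulse:
    """One detected contractile event (a fitted Gaussian component)."""

    pulse_id: str
    cell_id: str
    embryo_id: str
    amplitude: float        # a.u., Gaussian amplitude (pulse magnitude)
    center: float           # s, Gaussian mean (pulse timing)
    width: float            # s, Gaussian sigma in [10, 30]
    amplitude_bin: int | None = None
    response: np.ndarray | None = None
    response_valid: bool = False
    class_label: str = "uncategorized"
    membership: np.ndarray | None = None
    persistence: float | None = None
    curation_status: str = "unreviewed"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValidationError(f"pulse {self.pulse_id}: amplitude must be > 0")
        if not (10.0 - 1e-9 <= self.width <= 30.0 + 1e-9):
            raise ValidationError(
                f"pulse {self.pulse_id}: width {self.width:.3f}s outside [10, 30]s"
            )


PULSE_COLUMNS = [
    "pulse_id", "cell_id", "embryo_id", "amplitude", "center", "width",
    "amplitude_bin", "class_label", "persistence", "curation_status",
]


def pulses_to_frame(pulses: Iterable[Pulse]) -> pd.DataFrame:
    """Flatten Pulse objects into the standard pulses table."""
    rows = []
    for p in pulses:
        row = {k: getattr(p, k) for k in PULSE_COLUMNS}
        if p.membership is not None:
            for i, v in enumerate(np.asarray(p.membership, dtype=float)):
                row[f"membership_{i}"] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=None if rows else PULSE_COLUMNS)
    return df


def frame_to_pulses(df: pd.DataFrame) -> list[Pulse]:
    pulses = []
    for _, row in df.iterrows():
        pulses.append(
            Pulse(
                pulse_id=str(row["pulse_id"]),
                cell_id=str(row["cell_id"]),
                embryo_id=str(row["embryo_id"]),
                amplitude=float(row["amplitude"]),
                center=float(row["center"]),
                width=float(row["width"]),
                amplitude_bin=(
                    int(row["amplitude_bin"])
                    if "amplitude_bin" in row and pd.notna(row["amplitude_bin"])
                    else None
                ),
                class_label=str(row.get("class_label", "uncategorized")),
                persistence=(
                    float(row["persistence"])
                    if "persistence" in row and pd.notna(row["persistence"])
                    else None
                ),
                curation_status=str(row.get("curation_status", "unreviewed")),
            )
        )
    return pulses
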