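"""Division-orientation quantification relative to a reference axis.

During limb outgrowth the straight anterior-posterior compartment boundary
is parallel to — and an accurate proxy for — the proximal-distal axis, so
division orientation is measured as the angle between the daughter-daughter
separation vector and that boundary line.  Division axes are undirected:
angles are folded to [0°, 90°], binned into six 15° sectors and summarized
as rose-diagram percentages.  All angles are computed fully in 3D against
the axis direction; no projection plane is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DivisionEvent, LineageForest, division_events

__all__ = [
    "ReferenceAxis",
    "fit_reference_axis",
    "division_angle",
    "AngleSummary",
    "BIN_EDGES",
    "bin_angles",
    "orientation_by_stage",
]

BIN_EDGES = np.arange(0.0, 91.0, 15.0)


@dataclass(frozen=True)
class ReferenceAxis:
    """A line in space: unit direction vector and origin point (µm)."""

    direction: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source: str = "user"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / norm))

    @property
    def unit(self) -> np.ndarray:
        return np.asarray(self.direction)


def fit_reference_axis(points: Sequence[tuple[float, float, float]]) -> ReferenceAxis:
    """Total-least-squares line through a cloud of boundary-cell positions.

    The direction is the principal axis of the centred points (first right
    singular vector), the origin their centroid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("need at least two 3-D points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if np.allclose(centred, 0):
        raise ValueError("all points coincide; axis undefined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return ReferenceAxis(direction=tuple(vt[0]), origin=tuple(centroid), source="fitted")


def division_angle(event: DivisionEvent, axis: ReferenceAxis) -> float:
    """Angle (degrees, folded to [0, 90]) between a division and the axis.

    Computed from the separation vector of the two daughters at their
    first co-existing frame: 0° means the division axis is parallel to the
    reference boundary, 90° perpendicular.
    """
    v = np.asarray(event.daughter_a_pos, dtype=float) - np.asarray(
        event.daughter_b_pos, dtype=float
    )
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("coincident daughter positions; division axis undefined")
    cosang = abs(float(np.dot(v, axis.unit))) / norm
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class AngleSummary:
    """Rose-diagram summary: counts and percentages per 15° bin."""

    angles: np.ndarray
    counts: np.ndarray
    percentages: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def bin_angles(angles: Sequence[float]) -> AngleSummary:
    """Sort folded angles into the six 15° bins [0,15), ..., [75,90].

    The boundary value 90° belongs to the last bin.  Percentages sum to
    100 when any events are present.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 90):
        raise ValueError("angles must lie in [0, 90] degrees")
    idx = np.minimum(np.floor(arr / 15.0).astype(int), 5) if arr.size else np.array([], int)
    counts = np.bincount(idx, minlength=6) if arr.size else np.zeros(6, dtype=int)
    total = counts.sum()
    percentages = 100.0 * counts / total if total else np.zeros(6)
    return AngleSummary(angles=arr, counts=counts, percentages=percentages)


def orientation_by_stage(
    forest: LineageForest,
    axis: ReferenceAxis,
    stage_windows: Sequence[tuple[float, float]],
) -> dict[tuple[float, float], AngleSummary]:
    """One rose-diagram summary per developmental stage window.

    Windows are half-open ``[start, end)`` intervals in hours and must not
    overlap; division events outside every window are ignored.
    """
    windows = sorted(stage_windows)
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping stage windows ({a0},{a1}) and ({b0},{b1})")
    events = division_events(forest, strict=False)
    per_window: dict[tuple[float, float], list[float]] = {tuple(w): [] for w in windows}
    for e in events:
        for w0, w1 in windows:
            if w0 <= e.time_hours < w1:
                per_window[(w0, w1)].append(division_angle(e, axis))
                break
    return {w: bin_angles(a) for w, a in per_window.items()}


def angles_table(forest: LineageForest, axis: ReferenceAxis) -> pd.DataFrame:
    """Per-event angle table (event id, time, angle, bin index)."""
    rows = []
    for e in division_events(forest, strict=False):
        ang = division_angle(e, axis)
        rows.append(
            {
                "event_id": e.parent_cell_id,
                "time_hours": e.time_hours,
                "angle_deg": ang,
                "bin": int(min(ang // 15, 5)),
            }
        )
    return pd.DataFrame(rows, columns=["event_id", "time_hours", "angle_deg", "bin"])
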