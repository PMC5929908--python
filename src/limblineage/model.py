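"""Core data model for tracked cell lineages.

A lineage reconstruction is a *forest* of point detections ("spots") linked
over time: each detection marks one nucleus at one time-point, a link points
from a detection to its successor, and a detection with two successors marks
a cell division.  On top of this raw graph the module derives the biological
objects of interest: *cells* (branches between divisions), *division events*
(branch points with the positions of the two daughters), *cell-cycle lengths*
(branch lengths in hours), *clones* (all descendants of an ancestor up to a
time), relative founder birth times and cell-number growth curves.

Time is carried in hours; unless a detection states its own ``t_hours`` it is
derived from the frame index and the forest's frame interval (7.5 min by
default, the acquisition cadence of the light-sheet recordings this model
targets).  Links may span more than one frame: tracked nuclei are typically
annotated every few time-points except around mitosis.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

Position = tuple[float, float, float]

__all__ = [
    "CellDetection",
    "LineageForest",
    "Cell",
    "DivisionEvent",
    "GrowthCurve",
    "Violation",
    "ValidationReport",
    "validate_forest",
    "cells_of",
    "division_events",
    "cell_cycle_lengths",
    "relative_birth_times",
    "mean_relative_birth_times",
    "cell_count_curve",
    "extract_clone",
]


@dataclass(slots=True)
class CellDetection:
    """One tracked nucleus at one time-point."""

    id: int
    frame: int
    position: Position
    parent_id: int | None = None
    name: str = ""
    t_hours: float | None = None
    labels: dict[str, str] = field(default_factory=dict)


class LineageForest:
    """A collection of linked :class:`CellDetection` forming lineage trees.

    Parameters
    ----------
    detections
        Initial detections; order does not matter, parents may be added
        after children.
    frame_interval_minutes
        Physical duration of one frame; used to derive ``t_hours`` for
        detections that do not carry an explicit time.
    metadata
        Free-form mapping (provenance, units, effective tracking stride...).
    """

    def __init__(
        self,
        detections: Iterable[CellDetection] = (),
        frame_interval_minutes: float = 7.5,
        metadata: dict | None = None,
    ) -> None:
        if frame_interval_minutes <= 0:
            raise ValueError("frame_interval_minutes must be positive")
        self.frame_interval_minutes = float(frame_interval_minutes)
        self.metadata: dict = dict(metadata or {})
        self._det: dict[int, CellDetection] = {}
        self._children: dict[int, list[int]] = {}
        for det in detections:
            self.add(det)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._det)

    def __iter__(self) -> Iterator[CellDetection]:
        return iter(self._det.values())

    def __contains__(self, det_id: int) -> bool:
        return det_id in self._det

    def get(self, det_id: int) -> CellDetection:
        return self._det[det_id]

    # -- structure ----------------------------------------------------------

    def add(self, det: CellDetection) -> None:
        if det.id in self._det:
            raise ValueError(f"duplicate detection id {det.id}")
        if det.t_hours is None:
            det.t_hours = det.frame * self.frame_interval_minutes / 60.0
        self._det[det.id] = det
        self._children.setdefault(det.id, [])
        if det.parent_id is not None:
            self._children.setdefault(det.parent_id, []).append(det.id)

    def children(self, det_id: int) -> list[int]:
        """Ids of detections linked forward from ``det_id`` (existing only)."""
        return [c for c in self._children.get(det_id, ()) if c in self._det]

    def roots(self) -> list[CellDetection]:
        out = [d for d in self._det.values() if d.parent_id is None]
        out.sort(key=lambda d: (d.frame, d.id))
        return out

    def time_of(self, det_id: int) -> float:
        t = self._det[det_id].t_hours
        assert t is not None
        return t

    def max_frame(self) -> int:
        if not self._det:
            return 0
        return max(d.frame for d in self._det.values())

    def descendants(self, root_id: int) -> Iterator[int]:
        """Yield ``root_id`` and every detection reachable from it."""
        if root_id not in self._det:
            raise KeyError(f"unknown detection id {root_id}")
        queue = deque([root_id])
        while queue:
            cur = queue.popleft()
            yield cur
            queue.extend(self.children(cur))


@dataclass(slots=True)
class Violation:
    code: str
    detection_id: int
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "forest OK"
        return "\n".join(f"[{v.code}] #{v.detection_id}: {v.message}" for v in self.violations)


def validate_forest(forest: LineageForest) -> ValidationReport:
    """Check structural invariants, reporting (not raising) every violation.

    Checks: parent links point to existing detections, frames strictly
    increase along links, and no detection has more than two successors.
    """
    report = ValidationReport()
    for det in forest:
        if det.parent_id is not None:
            if det.parent_id not in forest:
                report.violations.append(
                    Violation("orphan-edge", det.id, f"parent {det.parent_id} does not exist")
                )
            else:
                parent = forest.get(det.parent_id)
                if parent.frame >= det.frame:
                    report.violations.append(
                        Violation(
                            "non-increasing-frame",
                            det.id,
                            f"frame {det.frame} not after parent frame {parent.frame}",
                        )
                    )
        n_children = len(forest.children(det.id))
        if n_children > 2:
            report.violations.append(
                Violation("out-degree", det.id, f"{n_children} successors (max 2)")
            )
    return report


@dataclass
class Cell:
    """A single cell: the chain of detections between two divisions.

    ``birth_t`` is the time of the parent's dividing detection (absent for
    roots, whose birth was not observed); ``division_t`` is the time of this
    cell's own dividing detection (absent for terminal or lost tracks).
    """

    cell_id: int
    branch: list[CellDetection]
    birth_t: float | None
    division_t: float | None

    @property
    def name(self) -> str:
        return self.branch[0].name

    @property
    def first_t(self) -> float:
        t = self.branch[0].t_hours
        assert t is not None
        return t

    @property
    def last_t(self) -> float:
        t = self.branch[-1].t_hours
        assert t is not None
        return t

    @property
    def divides(self) -> bool:
        return self.division_t is not None


@dataclass(slots=True)
class DivisionEvent:
    """A branch point: one detection with two tracked daughters."""

    parent_cell_id: int
    time_hours: float
    daughter_a_pos: Position
    daughter_b_pos: Position
    daughter_a_id: int
    daughter_b_id: int


@dataclass
class GrowthCurve:
    """Piecewise-constant cell count over time, relative to an anchor event."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _require_valid(forest: LineageForest) -> None:
    report = validate_forest(forest)
    if not report.ok:
        raise ValueError(f"invalid forest:\n{report}")


def _branch_from(forest: LineageForest, start_id: int) -> list[CellDetection]:
    """Detections of the cell starting at ``start_id`` up to its end."""
    branch = [forest.get(start_id)]
    while True:
        ch = forest.children(branch[-1].id)
        if len(ch) != 1:
            return branch
        branch.append(forest.get(ch[0]))


def cells_of(forest: LineageForest, strict: bool = True) -> list[Cell]:
    """Segment the forest into cells (branches between divisions).

    Every detection belongs to exactly one cell; a cell starts at a root or
    at a daughter of a division and ends at a division, a terminal
    detection, or a track loss.
    """
    if strict:
        _require_valid(forest)
    cells: list[Cell] = []
    stack: list[tuple[int, float | None]] = [(r.id, None) for r in reversed(forest.roots())]
    while stack:
        start_id, birth_t = stack.pop()
        branch = _branch_from(forest, start_id)
        last = branch[-1]
        ch = forest.children(last.id)
        division_t = forest.time_of(last.id) if len(ch) == 2 else None
        cells.append(Cell(cell_id=start_id, branch=branch, birth_t=birth_t, division_t=division_t))
        for daughter in reversed(ch):
            stack.append((daughter, division_t))
    return cells


def division_events(
    forest: LineageForest, within: int | None = None, strict: bool = True
) -> list[DivisionEvent]:
    """All division events, optionally restricted to the subtree of ``within``.

    Daughter positions are read at the first frame where both daughter
    branches carry a detection (the earliest observable proxy for the
    division axis); if the daughters were never annotated at a common frame,
    each daughter's first detection is used instead.
    """
    if strict:
        _require_valid(forest)
    if within is not None:
        ids: set[int] | None = set(forest.descendants(within))
    else:
        ids = None
    events: list[DivisionEvent] = []
    for det in sorted(forest, key=lambda d: (d.frame, d.id)):
        if ids is not None and det.id not in ids:
            continue
        ch = forest.children(det.id)
        if len(ch) != 2:
            continue
        branch_a = _branch_from(forest, ch[0])
        branch_b = _branch_from(forest, ch[1])
        frames_a = {d.frame: d for d in branch_a}
        frames_b = {d.frame: d for d in branch_b}
        common = sorted(set(frames_a) & set(frames_b))
        if common:
            da, db = frames_a[common[0]], frames_b[common[0]]
        else:
            da, db = branch_a[0], branch_b[0]
        events.append(
            DivisionEvent(
                parent_cell_id=det.id,
                time_hours=forest.time_of(det.id),
                daughter_a_pos=da.position,
                daughter_b_pos=db.position,
                daughter_a_id=da.id,
                daughter_b_id=db.id,
            )
        )
    return events


def cell_cycle_lengths(forest: LineageForest) -> pd.DataFrame:
    """Cell-cycle length (branch length, hours) for every cell.

    Cells whose birth (roots) or division (terminal/lost tracks) was not
    observed get ``ccl_hours = NaN`` and ``applicable = False``.
    """
    rows = []
    for cell in cells_of(forest):
        applicable = cell.birth_t is not None and cell.division_t is not None
        ccl = cell.division_t - cell.birth_t if applicable else np.nan
        rows.append(
            {
                "cell_id": cell.cell_id,
                "name": cell.name,
                "ccl_hours": ccl,
                "applicable": applicable,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "name", "ccl_hours", "applicable"])


def relative_birth_times(
    forest: LineageForest, founder_ids: Sequence[int] | None = None
) -> pd.DataFrame:
    """Founder birth times on a 0-100% scale.

    The earliest-born founder maps to 0%, the latest to 100%, all others
    linearly in between.  Birth time is the time of the founder's first
    detection.
    """
    if founder_ids is None:
        founder_ids = [r.id for r in forest.roots()]
    founder_ids = list(founder_ids)
    if len(founder_ids) < 2:
        raise ValueError("need at least two founders")
    births = np.array([forest.time_of(i) for i in founder_ids])
    t_min, t_max = births.min(), births.max()
    if t_max == t_min:
        raise ValueError("all founder birth times are equal; relative scale undefined")
    percent = 100.0 * (births - t_min) / (t_max - t_min)
    return pd.DataFrame(
        {
            "founder_id": founder_ids,
            "name": [forest.get(i).name for i in founder_ids],
            "birth_t_hours": births,
            "percent": percent,
        }
    )


def mean_relative_birth_times(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-founder relative birth times across replicate limbs.

    Founders are matched by ``name`` (their identity label); the result is
    the mean of the per-limb percentages for each homologous founder.
    """
    if not tables:
        raise ValueError("no tables given")
    merged = pd.concat([t[["name", "percent"]] for t in tables])
    out = merged.groupby("name", sort=True)["percent"].mean().reset_index()
    return out


def cell_count_curve(forest: LineageForest, anchor_cell_id: int) -> GrowthCurve:
    """Number of concurrently alive tracked cells over time.

    Times are measured from the division of the anchor cell (the cell whose
    first detection is ``anchor_cell_id``).  A cell is alive from its birth
    (parent division; first detection for roots) until its own division, or
    until its last detection if the track ends early.  Tracks that survive
    to the final recorded frame never decrement the count.
    """
    cells = cells_of(forest)
    by_id = {c.cell_id: c for c in cells}
    det_to_cell: dict[int, Cell] = {}
    for c in cells:
        for d in c.branch:
            det_to_cell[d.id] = c
    if anchor_cell_id not in det_to_cell:
        raise KeyError(f"unknown anchor detection {anchor_cell_id}")
    anchor = det_to_cell[anchor_cell_id]
    if anchor.division_t is None:
        raise ValueError(f"anchor cell {anchor.cell_id} never divides")
    t_anchor = anchor.division_t

    last_frame = forest.max_frame()
    deltas: dict[float, float] = {}
    for c in cells:
        start = c.birth_t if c.birth_t is not None else c.first_t
        deltas[start] = deltas.get(start, 0.0) + 1.0
        if c.divides:
            deltas[c.division_t] = deltas.get(c.division_t, 0.0) - 1.0
        elif c.branch[-1].frame < last_frame:  # lost track
            deltas[c.last_t] = deltas.get(c.last_t, 0.0) - 1.0
    times = np.array(sorted(deltas))
    counts = np.cumsum([deltas[t] for t in times])
    return GrowthCurve(times=times - t_anchor, counts=counts)


def extract_clone(forest: LineageForest, ancestor_id: int, t_end_hours: float) -> set[int]:
    """Detection ids of the digital clone of ``ancestor_id`` up to ``t_end_hours``.

    The clone contains the ancestor detection and every descendant detection
    whose time does not exceed ``t_end_hours``; clones of sibling ancestors
    are disjoint by construction.
    """
    if ancestor_id not in forest:
        raise KeyError(f"unknown detection id {ancestor_id}")
    t0 = forest.time_of(ancestor_id)
    if t_end_hours < t0 - 1e-9:
        raise ValueError("t_end_hours precedes the ancestor's own time")
    return {i for i in forest.descendants(ancestor_id) if forest.time_of(i) <= t_end_hours + 1e-9}
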