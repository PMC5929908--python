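"""Lineage-tree distance based on division-time sets.

Each founder's lineage tree is reduced to the multiset L of times at which
divisions occurred in its subtree.  Two trees Lx, Ly are compared through
two components:

* ``δn = |Card(Lx) − Card(Ly)|`` — the difference in division counts;
* ``δt`` — the mean absolute difference of division times under the
  one-to-one pairing P* that minimizes it (an optimal rectangular
  assignment covering the smaller set).

Within a batch of pairwise comparisons both components are normalized by
the batch maxima ``nt`` and ``nn`` and combined into the dimensionless
distance Δ.  The printed source formula for the combination is ambiguous,
so two readings are provided: the default Euclidean norm

    Δ = sqrt((δt/nt)² + (δn/nn)²)

and the arithmetic mean ``Δ = (δt/nt + δn/nn)/2``.

Trees from replicate limbs developing at different speeds are registered
before comparison by a linear temporal scale factor applied to the
division times (1.6 between the two limbs that motivated this module).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import LineageForest, division_events

__all__ = [
    "DivisionTimeSet",
    "Pairing",
    "NormalizationConstants",
    "DistanceResult",
    "first_division_time",
    "build_division_time_set",
    "delta_n",
    "optimal_pairing_delta_t",
    "normalization_constants",
    "lineage_distance",
    "distance_matrix",
    "cross_distance_matrix",
    "average_tree",
]

COMBINE_MODES = ("euclidean", "mean")


@dataclass(frozen=True)
class DivisionTimeSet:
    """A founder's lineage tree reduced to its multiset of division times."""

    founder_id: str
    times: tuple[float, ...]
    t_cut: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(sorted(float(t) for t in self.times)))
        if any(t < -1e-9 for t in self.times):
            raise ValueError("division times must be non-negative")
        if any(t > self.t_cut + 1e-9 for t in self.times):
            raise ValueError("division times must not exceed t_cut")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Pairing:
    """One-to-one correspondence between division times of two trees."""

    pairs: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class NormalizationConstants:
    """Batch maxima of δt (hours) and δn (count) used to normalize Δ."""

    nt: float
    nn: float


@dataclass(frozen=True)
class DistanceResult:
    delta_t: float
    delta_n: int
    pairing: Pairing
    delta: float


def first_division_time(forest: LineageForest) -> float | None:
    """Time of the first tracked division (the default temporal anchor)."""
    events = division_events(forest, strict=False)
    if not events:
        return None
    return min(e.time_hours for e in events)


def build_division_time_set(
    forest: LineageForest,
    founder_id: int,
    t_cut_hours: float,
    scale: float = 1.0,
    t_origin: float | None = None,
) -> DivisionTimeSet:
    """Collect the division times of a founder's subtree.

    Times are expressed relative to ``t_origin`` (the forest's first
    tracked division by default), multiplied by ``scale`` for temporal
    registration, and truncated at ``t_cut_hours``.  The set's identity
    label is the founder detection's name (falling back to its id).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if founder_id not in forest:
        raise KeyError(f"unknown founder detection {founder_id}")
    if t_origin is None:
        t_origin = first_division_time(forest)
        if t_origin is None:
            t_origin = 0.0
    events = division_events(forest, within=founder_id, strict=False)
    times = [scale * (e.time_hours - t_origin) for e in events]
    times = [t for t in times if -1e-9 <= t <= t_cut_hours + 1e-9]
    det = forest.get(founder_id)
    label = det.name or str(founder_id)
    return DivisionTimeSet(founder_id=label, times=tuple(times), t_cut=t_cut_hours, scale=scale)


def delta_n(Lx: DivisionTimeSet, Ly: DivisionTimeSet) -> int:
    """Absolute difference in the number of divisions of the two trees."""
    return abs(len(Lx) - len(Ly))


def optimal_pairing_delta_t(
    Lx: DivisionTimeSet, Ly: DivisionTimeSet
) -> tuple[Pairing, float]:
    """Minimal mean absolute division-time difference over maximal pairings.

    The pairing is a one-to-one matching covering the smaller set, found by
    an exact rectangular linear-assignment solve on the cost matrix of
    absolute time differences (minimizing the sum over fixed-size matchings
    equals minimizing the mean).  When either set is empty δt is 0: the
    disparity is then carried entirely by δn.
    """
    tx = np.asarray(Lx.times, dtype=float)
    ty = np.asarray(Ly.times, dtype=float)
    if tx.size == 0 or ty.size == 0:
        return Pairing(()), 0.0
    cost = np.abs(tx[:, None] - ty[None, :])
    ri, ci = linear_sum_assignment(cost)
    pairs = tuple((float(tx[i]), float(ty[j])) for i, j in zip(ri, ci))
    dt = float(cost[ri, ci].sum() / len(ri))
    return Pairing(pairs), dt


def normalization_constants(
    pairs_batch: Iterable[tuple[DivisionTimeSet, DivisionTimeSet]],
) -> NormalizationConstants:
    """Maximum δt and δn observed over a batch of comparisons."""
    nt = nn = -1.0
    for Lx, Ly in pairs_batch:
        _, dt = optimal_pairing_delta_t(Lx, Ly)
        nt = max(nt, dt)
        nn = max(nn, float(delta_n(Lx, Ly)))
    if nt < 0:
        raise ValueError("empty comparison batch")
    return NormalizationConstants(nt=nt, nn=nn)


def lineage_distance(
    Lx: DivisionTimeSet,
    Ly: DivisionTimeSet,
    norms: NormalizationConstants,
    combine: str = "euclidean",
) -> DistanceResult:
    """Normalized combined distance Δ between two division-time sets.

    A zero normalization constant (an all-identical batch) forces the
    corresponding component to 0, avoiding 0/0.
    """
    if combine not in COMBINE_MODES:
        raise ValueError(f"unknown combine mode {combine!r}; choose from {COMBINE_MODES}")
    pairing, dt = optimal_pairing_delta_t(Lx, Ly)
    dn = delta_n(Lx, Ly)
    ut = dt / norms.nt if norms.nt > 0 else 0.0
    un = dn / norms.nn if norms.nn > 0 else 0.0
    if combine == "euclidean":
        delta = float(np.hypot(ut, un))
    else:
        delta = (ut + un) / 2.0
    return DistanceResult(delta_t=dt, delta_n=dn, pairing=pairing, delta=delta)


def distance_matrix(
    sets: Sequence[DivisionTimeSet], combine: str = "euclidean"
) -> tuple[pd.DataFrame, NormalizationConstants]:
    """All-pairs Δ matrix over a collection of division-time sets.

    The normalization constants are computed over exactly this batch (all
    ordered pairs), so Δ values from different batches are not directly
    comparable.  Returns a symmetric, zero-diagonal DataFrame indexed by
    founder ids, together with the constants.
    """
    if len(sets) < 2:
        raise ValueError("need at least two division-time sets")
    norms = normalization_constants(itertools.product(sets, sets))
    n = len(sets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = lineage_distance(sets[i], sets[j], norms, combine).delta
    labels = [s.founder_id for s in sets]
    return pd.DataFrame(mat, index=labels, columns=labels), norms


def cross_distance_matrix(
    row_sets: Sequence[DivisionTimeSet],
    col_sets: Sequence[DivisionTimeSet],
    combine: str = "euclidean",
) -> tuple[pd.DataFrame, NormalizationConstants]:
    """Δ matrix between founders of two limbs (rows × columns).

    Normalization constants come from the full rows × columns batch, the
    same convention as :func:`distance_matrix`.
    """
    if not row_sets or not col_sets:
        raise ValueError("both set collections must be non-empty")
    norms = normalization_constants(itertools.product(row_sets, col_sets))
    mat = np.zeros((len(row_sets), len(col_sets)))
    for i, Lx in enumerate(row_sets):
        for j, Ly in enumerate(col_sets):
            mat[i, j] = lineage_distance(Lx, Ly, norms, combine).delta
    return (
        pd.DataFrame(
            mat,
            index=[s.founder_id for s in row_sets],
            columns=[s.founder_id for s in col_sets],
        ),
        norms,
    )


def average_tree(L1x: DivisionTimeSet, L2x: DivisionTimeSet) -> DivisionTimeSet:
    """Union-average tree of one founder observed in two registered limbs.

    Defined as the multiset union of the two time collections (duplicates
    retained so that the cardinality reflects the total number of observed
    divisions).  Both inputs must describe the same founder.
    """
    if L1x.founder_id != L2x.founder_id:
        raise ValueError(
            f"founder identity mismatch: {L1x.founder_id!r} vs {L2x.founder_id!r}"
        )
    return DivisionTimeSet(
        founder_id=L1x.founder_id,
        times=L1x.times + L2x.times,
        t_cut=max(L1x.t_cut, L2x.t_cut),
        scale=1.0,
    )
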