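"""Shared fixtures: hand-built forests, random-forest factory, oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from limblineage import (
    CellDetection,
    DivisionTimeSet,
    LineageForest,
    SyntheticLimbConfig,
    default_founder_grid,
    generate_limb,
)


def build_forest(specs, frame_interval_minutes=7.5):
    """Build a forest from (id, frame, parent_id) or (id, frame, parent_id, pos) tuples."""
    forest = LineageForest(frame_interval_minutes=frame_interval_minutes)
    for spec in specs:
        det_id, frame, parent = spec[:3]
        pos = spec[3] if len(spec) > 3 else (float(det_id), 0.0, 0.0)
        forest.add(CellDetection(id=det_id, frame=frame, position=pos, parent_id=parent))
    return forest


@pytest.fixture
def one_division_forest():
    """Root tracked 3 frames, divides, daughters tracked 2 frames each."""
    return build_forest(
        [
            (1, 0, None),
            (2, 1, 1),
            (3, 2, 2),  # divides here
            (4, 3, 3),
            (5, 4, 4),
            (6, 3, 3),
            (7, 4, 6),
        ]
    )


def make_random_forest(rng: np.random.Generator, n_roots: int = 3, max_depth: int = 3):
    """Random valid forest: variable branch lengths, gaps, divisions, labels."""
    forest = LineageForest()
    counter = itertools.count(1)

    def grow(parent_id, frame, depth):
        cur, f = parent_id, frame
        for _ in range(int(rng.integers(1, 5))):
            det_id = next(counter)
            labels = {}
            if rng.random() < 0.3:
                labels = {"parasegment": "E4", "row": str(rng.integers(0, 4))}
            forest.add(
                CellDetection(
                    id=det_id,
                    frame=f,
                    position=tuple(np.round(rng.normal(0, 25, 3), 4)),
                    parent_id=cur,
                    name=f"cell{det_id}",
                    labels=labels,
                )
            )
            cur = det_id
            f += int(rng.integers(1, 4))  # gaps allowed
        if depth > 0 and rng.random() < 0.7:
            grow(cur, f, depth - 1)
            grow(cur, f + int(rng.integers(1, 3)), depth - 1)

    for _ in range(n_roots):
        grow(None, int(rng.integers(0, 3)), max_depth)
    return forest


@pytest.fixture
def random_forest_factory():
    return make_random_forest


def forests_equal(a: LineageForest, b: LineageForest, pos_tol: float = 1e-6) -> bool:
    if {d.id for d in a} != {d.id for d in b}:
        return False
    for det in a:
        other = b.get(det.id)
        if (det.frame, det.parent_id, det.name, det.labels) != (
            other.frame,
            other.parent_id,
            other.name,
            other.labels,
        ):
            return False
        if np.max(np.abs(np.subtract(det.position, other.position))) > pos_tol:
            return False
    return True


def brute_force_delta_t(Lx: DivisionTimeSet, Ly: DivisionTimeSet) -> float:
    """Exhaustive oracle: minimal mean |Δt| over all maximal injective pairings."""
    tx, ty = list(Lx.times), list(Ly.times)
    if not tx or not ty:
        return 0.0
    if len(tx) > len(ty):
        tx, ty = ty, tx
    best = np.inf
    for perm in itertools.permutations(ty, len(tx)):
        best = min(best, float(np.mean([abs(x - y) for x, y in zip(tx, perm)])))
    return best


def random_time_set(rng: np.random.Generator, max_size: int = 6) -> DivisionTimeSet:
    n = int(rng.integers(0, max_size + 1))
    times = np.round(rng.uniform(0, 40, n), 3)
    return DivisionTimeSet(founder_id=f"f{rng.integers(1e6)}", times=tuple(times), t_cut=40.0)


@pytest.fixture(scope="session")
def small_limb():
    """A reduced synthetic limb (12 founders, 30 h) shared across tests."""
    config = SyntheticLimbConfig(
        founders=default_founder_grid()[:12], t_end_hours=30.0, seed=7
    )
    forest, truth = generate_limb(config)
    return config, forest, truth


@pytest.fixture(scope="session")
def default_limb():
    """One full-size limb under default study conditions."""
    config = SyntheticLimbConfig(seed=1)
    forest, truth = generate_limb(config)
    return config, forest, truth
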