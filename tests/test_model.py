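"""Lineage data model: validation, cell segmentation, clones, CCLs, growth."""

import numpy as np
import pandas as pd
import pytest

from limblineage import (
    CellDetection,
    LineageForest,
    cell_count_curve,
    cell_cycle_lengths,
    cells_of,
    division_events,
    extract_clone,
    mean_relative_birth_times,
    relative_birth_times,
    validate_forest,
)

from conftest import build_forest, make_random_forest


class TestValidation:
    def test_well_formed_chain_is_clean(self):
        forest = build_forest([(1, 0, None), (2, 1, 1), (3, 2, 2)])
        assert validate_forest(forest).ok

    def test_three_children_flagged_as_out_degree(self):
        forest = build_forest([(1, 0, None), (2, 1, 1), (3, 1, 1), (4, 1, 1)])
        report = validate_forest(forest)
        assert [v.code for v in report.violations] == ["out-degree"]

    def test_equal_frame_link_flagged(self):
        forest = build_forest([(1, 5, None), (2, 5, 1)])
        report = validate_forest(forest)
        assert [v.code for v in report.violations] == ["non-increasing-frame"]

    def test_orphan_edge_flagged(self):
        forest = build_forest([(1, 0, None), (2, 1, 99)])
        assert [v.code for v in validate_forest(forest).violations] == ["orphan-edge"]


class TestCells:
    @pytest.mark.parametrize(
        "specs,expected",
        [
            # one division -> parent + two daughters
            ([(1, 0, None), (2, 1, 1), (3, 2, 2), (4, 2, 2)], 3),
            # unbranched 10-frame track
            ([(i, i - 1, i - 1 if i > 1 else None) for i in range(1, 11)], 1),
            # two roots, one division each
            (
                [(1, 0, None), (2, 1, 1), (3, 1, 1), (10, 0, None), (11, 1, 10), (12, 1, 10)],
                6,
            ),
        ],
    )
    def test_cell_counts(self, specs, expected):
        assert len(cells_of(build_forest(specs))) == expected

    def test_every_detection_in_exactly_one_cell(self):
        for seed in range(5):
            forest = make_random_forest(np.random.default_rng(seed))
            seen = [d.id for c in cells_of(forest) for d in c.branch]
            assert sorted(seen) == sorted(d.id for d in forest)

    def test_birth_and_division_endpoints(self, one_division_forest):
        cells = {c.cell_id: c for c in cells_of(one_division_forest)}
        root = cells[1]
        assert root.birth_t is None  # unobserved birth
        assert root.division_t == pytest.approx(2 * 7.5 / 60)
        for daughter in (4, 6):
            assert cells[daughter].birth_t == root.division_t
            assert cells[daughter].division_t is None


class TestDivisionEvents:
    def test_counts(self, one_division_forest):
        assert len(division_events(one_division_forest)) == 1
        chain = build_forest([(1, 0, None), (2, 1, 1), (3, 2, 2)])
        assert division_events(chain) == []

    def test_synthetic_event_count_matches_programmed_divisions(self, small_limb):
        _, forest, truth = small_limb
        assert len(division_events(forest)) == len(truth.divisions)

    def test_daughter_positions_taken_at_first_shared_frame(self):
        forest = build_forest(
            [
                (1, 0, None, (0.0, 0.0, 0.0)),
                (2, 1, 1, (1.0, 0.0, 0.0)),
                (3, 1, 1, (-1.0, 0.0, 0.0)),
            ]
        )
        (event,) = division_events(forest)
        assert event.daughter_a_pos == (1.0, 0.0, 0.0)
        assert event.daughter_b_pos == (-1.0, 0.0, 0.0)
        assert event.time_hours == 0.0


class TestCellCycleLengths:
    def test_observed_cycle_is_division_minus_birth(self):
        # root divides at frame 8, daughter divides at frame 16, grandkids end
        specs = [(1, 0, None), (2, 8, 1), (3, 9, 2), (4, 16, 3), (5, 17, 4), (6, 17, 4), (7, 9, 2)]
        table = cell_cycle_lengths(build_forest(specs)).set_index("cell_id")
        assert not table.loc[1, "applicable"]  # root: birth unobserved
        assert table.loc[3, "applicable"]
        assert table.loc[3, "ccl_hours"] == pytest.approx(8 * 7.5 / 60)

    def test_path_cycle_sums_telescope(self, small_limb):
        # along any root-to-leaf path, the observed cycles sum to
        # (last division time - first division time)
        _, forest, _ = small_limb
        cells = {c.cell_id: c for c in cells_of(forest)}
        det_to_cell = {d.id: c for c in cells.values() for d in c.branch}
        for root_cell in [c for c in cells.values() if c.birth_t is None][:5]:
            path = [root_cell]
            while path[-1].divides:
                child_id = forest.children(path[-1].branch[-1].id)[0]
                path.append(det_to_cell[child_id])
            observed = [c for c in path if c.birth_t is not None and c.divides]
            if observed:
                total = sum(c.division_t - c.birth_t for c in observed)
                span = observed[-1].division_t - observed[0].birth_t
                assert total == pytest.approx(span)


class TestRelativeBirthTimes:
    def test_linear_mapping(self):
        forest = build_forest([(1, 0, None), (2, 40, None), (3, 80, None)])
        table = relative_birth_times(forest).set_index("founder_id")
        assert list(table["percent"]) == [0.0, 50.0, 100.0]

    def test_zero_range_rejected(self):
        forest = build_forest([(1, 0, None), (2, 0, None)])
        with pytest.raises(ValueError, match="equal"):
            relative_birth_times(forest)

    def test_replicate_average_is_per_founder_mean(self):
        t1 = pd.DataFrame({"name": ["a", "b"], "percent": [40.0, 0.0]})
        t2 = pd.DataFrame({"name": ["a", "b"], "percent": [60.0, 10.0]})
        out = mean_relative_birth_times([t1, t2]).set_index("name")
        assert out.loc["a", "percent"] == 50.0
        assert out.loc["b", "percent"] == 5.0


class TestGrowthCurve:
    def test_count_steps_from_one_to_two_at_anchor_division(self, one_division_forest):
        curve = cell_count_curve(one_division_forest, anchor_cell_id=1)
        idx = np.searchsorted(curve.times, 0.0, side="right") - 1
        assert curve.counts[idx] == 2
        assert curve.counts[idx - 1] == 1

    def test_anchor_that_never_divides_rejected(self):
        forest = build_forest([(1, 0, None), (2, 1, 1), (3, 2, 2)])
        with pytest.raises(ValueError, match="divides"):
            cell_count_curve(forest, 1)

    def test_conservation_against_event_bookkeeping(self):
        # count(t) = 1 + divisions<=t - terminations<=t for one founder
        rng = np.random.default_rng(11)
        forest = make_random_forest(rng, n_roots=1, max_depth=4)
        cells = cells_of(forest)
        anchor = min((c for c in cells if c.divides), key=lambda c: c.division_t)
        curve = cell_count_curve(forest, anchor.cell_id)
        last_frame = forest.max_frame()
        div_times = sorted(c.division_t - anchor.division_t for c in cells if c.divides)
        term_times = sorted(
            c.last_t - anchor.division_t
            for c in cells
            if not c.divides and c.branch[-1].frame < last_frame
        )
        for t in np.linspace(curve.times[0], curve.times[-1] - 1e-6, 17):
            expected = (
                1
                + np.searchsorted(div_times, t, side="right")
                - np.searchsorted(term_times, t, side="right")
            )
            idx = np.searchsorted(curve.times, t + 1e-12, side="right") - 1
            assert curve.counts[idx] == expected

    def test_final_count_matches_programmed_cell_number(self, small_limb):
        _, forest, truth = small_limb
        cells = cells_of(forest)
        anchor = min((c for c in cells if c.divides), key=lambda c: c.division_t)
        curve = cell_count_curve(forest, anchor.cell_id)
        n_alive = truth.cells["division_t"].isna().sum()
        assert curve.counts[-1] == n_alive


class TestClones:
    def test_leaf_clone_is_singleton(self, one_division_forest):
        assert extract_clone(one_division_forest, 5, t_end_hours=100.0) == {5}

    def test_horizon_at_own_time_keeps_only_self(self, one_division_forest):
        t0 = one_division_forest.time_of(1)
        assert extract_clone(one_division_forest, 1, t_end_hours=t0) == {1}

    def test_daughter_clones_partition_parent_clone(self):
        for seed in range(4):
            forest = make_random_forest(np.random.default_rng(seed), n_roots=1, max_depth=3)
            t_end = forest.max_frame() * forest.frame_interval_minutes / 60
            for event in division_events(forest):
                first_a, first_b = forest.children(event.parent_cell_id)
                a = extract_clone(forest, first_a, t_end)
                b = extract_clone(forest, first_b, t_end)
                assert not a & b
                # clone of the branching detection = itself plus the two
                # daughter clones
                parent_clone = extract_clone(forest, event.parent_cell_id, t_end)
                assert a | b == parent_clone - {event.parent_cell_id}

    def test_unknown_ancestor_and_bad_horizon(self, one_division_forest):
        with pytest.raises(KeyError):
            extract_clone(one_division_forest, 999, 10.0)
        with pytest.raises(ValueError):
            extract_clone(one_division_forest, 5, 0.0)


def test_duplicate_detection_ids_rejected():
    forest = LineageForest()
    forest.add(CellDetection(id=1, frame=0, position=(0, 0, 0)))
    with pytest.raises(ValueError, match="duplicate"):
        forest.add(CellDetection(id=1, frame=1, position=(0, 0, 0)))
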