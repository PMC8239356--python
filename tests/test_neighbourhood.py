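"""Padded-box neighbour discovery, repeat chaining and CSV export."""

import numpy as np
import pandas as pd
import pytest

from astral import find_neighbours, find_repeats, generate_csv, projection_overlap


def pairs(neighbours):
    return {(n.event_id, n.neighbour_id) for n in neighbours}


class TestFindNeighbours:
    @pytest.mark.parametrize("sep,expected", [(49, True), (50, True), (51, False)])
    def test_xy_tolerance_boundary_inclusive(self, make_table, sep, expected):
        table = make_table(
            [np.array([[10, 2, 5]]), np.array([[10, 2, 5 + sep]])], shape=(20, 5, 80)
        )
        found = pairs(find_neighbours(table, 50, 5))
        assert (found == {(1, 2), (2, 1)}) is expected

    @pytest.mark.parametrize("gap,expected", [(5, True), (6, False)])
    def test_t_tolerance_boundary_inclusive(self, make_table, gap, expected):
        table = make_table(
            [np.array([[10, 2, 2]]), np.array([[10 + gap, 2, 2]])], shape=(30, 5, 5)
        )
        found = pairs(find_neighbours(table, 50, 5))
        assert (found == {(1, 2), (2, 1)}) is expected

    def test_chain_without_transitivity(self, make_table):
        # A-B and B-C within reach, A-C not: records are exactly the 4
        # qualifying ordered pairs
        table = make_table(
            [np.array([[5, 2, 0]]), np.array([[5, 2, 40]]), np.array([[5, 2, 80]])],
            shape=(10, 5, 100),
        )
        assert pairs(find_neighbours(table, 50, 5)) == {(1, 2), (2, 1), (2, 3), (3, 2)}

    def test_asymmetric_extents_give_asymmetric_relation(self, make_table):
        # A left-heavy event's centred box over-extends on its light side
        # (half-width = max centroid-to-extreme distance), so it can reach a
        # single-voxel event whose own small box does not reach back.
        skewed = np.array([[5, 2, x] for x in (60, 61, 62, 63, 64, 80)])
        lone = np.array([[5, 2, 5]])
        table = make_table([skewed, lone], shape=(10, 5, 100))
        # skewed: centroid x=65, half-width 15+50 -> box [0, 130] contains x=5;
        # lone: box [-45, 55] contains no skewed voxel (min is 60)
        assert pairs(find_neighbours(table, 50, 5)) == {(1, 2)}

    def test_zero_tolerances_box_is_own_extent(self, make_table):
        table = make_table(
            [np.array([[3, 2, 2], [3, 2, 3]]), np.array([[3, 2, 4]])], shape=(6, 5, 8)
        )
        found = pairs(find_neighbours(table, 0, 0))
        # event 1 centroid x=2.5, half-width 0.5: reaches x<=3, not 4;
        # event 2's zero box contains only itself
        assert found == set()

    def test_exhaustive_oracle_equivalence(self, make_random_events, neighbour_oracle):
        rng = np.random.default_rng(10)
        for trial in range(5):
            table = make_random_events(rng, 15)
            tol_xy, tol_t = [(50, 5), (20, 2), (5, 0), (0, 3), (80, 10)][trial]
            ours = pairs(find_neighbours(table, tol_xy, tol_t))
            assert ours == neighbour_oracle(table, tol_xy, tol_t)

    def test_record_fields(self, make_table):
        table = make_table(
            [np.array([[4, 2, 0]]), np.array([[7, 2, 30], [7, 3, 31]])],
            shape=(20, 6, 60),
        )
        recs = [n for n in find_neighbours(table, 50, 5) if n.event_id == 1]
        assert len(recs) == 1
        n = recs[0]
        assert n.neighbour_id == 2 and n.delta_onset == 3
        assert n.neighbour_extent_x == 2 and n.neighbour_extent_y == 2
        assert n.neighbour_extent_t == 1
        assert n.centre_distance_xy == pytest.approx(np.hypot(0.5, 30.5))


class TestFindRepeats:
    def _classified(self, table, threshold=0.8):
        neighbours = find_neighbours(table, 50, 5)
        return find_repeats(neighbours, table, threshold)

    def test_identical_projections_are_repeats(self, make_table):
        a = np.array([[2, 3, x] for x in range(5)])
        b = np.array([[6, 3, x] for x in range(5)])
        cls = self._classified(make_table([a, b], shape=(12, 6, 10)))
        assert cls.category == {1: "repeat", 2: "repeat"}
        assert cls.chains == {1: (1, 2)}

    def test_exact_threshold_overlap_is_single(self, make_table):
        # equal-area footprints overlapping by exactly 0.8: strict "more
        # than" keeps both single
        a = np.array([[2, 3, x] for x in range(0, 20)])
        b = np.array([[6, 3, x] for x in range(4, 24)])
        table = make_table([a, b], shape=(12, 6, 30))
        assert projection_overlap(table[0], table[1]) == 0.8
        assert self._classified(table).category == {1: "single", 2: "single"}

    def test_disjoint_projections_are_single(self, make_table):
        a = np.array([[2, 3, 0]])
        b = np.array([[4, 3, 9]])
        cls = self._classified(make_table([a, b], shape=(8, 6, 12)))
        assert cls.category == {1: "single", 2: "single"}
        assert cls.chains == {}

    def test_three_member_chain_and_gaps(self, make_table):
        sets = [np.array([[t, 3, x] for x in range(6)]) for t in (10, 30, 55)]
        table = make_table(sets, shape=(60, 6, 8))
        neighbours = find_neighbours(table, 50, 50)  # generous time tolerance
        cls = find_repeats(neighbours, table, 0.8)
        assert cls.chains == {1: (1, 2, 3)}
        assert cls.inter_repeat_gaps[1] == (20, 25)

    def test_overlap_fraction_symmetric(self, make_table):
        a = np.array([[2, 3, x] for x in range(0, 10)])
        b = np.array([[6, 3, x] for x in range(5, 25)])  # different areas
        table = make_table([a, b], shape=(12, 6, 30))
        assert projection_overlap(table[0], table[1]) == projection_overlap(
            table[1], table[0]
        )
        assert projection_overlap(table[0], table[1]) == 0.5  # 5 / min(10, 20)

    def test_raising_threshold_never_adds_repeats(self, make_random_events):
        rng = np.random.default_rng(11)
        table = make_random_events(rng, 12, shape=(20, 40, 40))
        neighbours = find_neighbours(table, 50, 10)
        counts = [
            find_repeats(neighbours, table, th).n_repeats
            for th in (0.1, 0.3, 0.5, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)


class TestGenerateCsv:
    def test_chain_and_singles_files(self, make_table, tmp_path):
        chain = [np.array([[t, 3, x] for x in range(6)]) for t in (10, 30, 55)]
        singles = [np.array([[5, 20, 2]]), np.array([[40, 25, 2]])]
        table = make_table(chain + singles, shape=(60, 30, 8))
        neighbours = find_neighbours(table, 50, 50)
        cls = find_repeats(neighbours, table, 0.8)
        files = generate_csv(neighbours, cls, table, tmp_path)
        repeats = pd.read_csv(files["repeats"])
        assert len(repeats) == 3 and repeats["chain_id"].nunique() == 1
        assert repeats["gap_to_previous_frames"].dropna().tolist() == [20.0, 25.0]
        assert len(pd.read_csv(files["singles"])) == 2

    def test_empty_inputs_header_only(self, make_table, tmp_path):
        table = make_table([np.array([[1, 1, 1]])], shape=(4, 3, 3))
        cls = find_repeats([], table, 0.8)
        files = generate_csv([], cls, table, tmp_path)
        frame = pd.read_csv(files["neighbours"])
        assert len(frame) == 0 and "event_id" in frame.columns
        assert len(pd.read_csv(files["repeats"])) == 0
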