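import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import habsuit as hb
from habsuit.overlap import DEFAULT_LEVEL_WEIGHTS, OptimalMask
from habsuit.spatial import GridSpec, HsiSurface


GRID = GridSpec(lat_range=(27, 28), lon_range=(122, 123), resolution=0.5)


def _surface(values, in_hull=None, species="sp", season="spring"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "lat": 27.0,
            "lon": 122.0,
            "value": values,
            "in_hull": in_hull if in_hull is not None else np.ones(n, dtype=bool),
        }
    )
    return HsiSurface(species=species, season=season, grid_spec=GRID, cells=cells)


def _mask(cells, species="sp", season="spring", grid_id=("g",)):
    return OptimalMask(species=species, season=season, cells=frozenset(cells),
                       grid_id=grid_id, threshold=0.7)


class TestExtractOptimal:
    def test_strictly_greater_than_threshold(self):
        m = hb.extract_optimal(_surface([0.70, 0.71, 0.69]), threshold=0.7)
        assert m.cells == {1}

    def test_all_below_threshold_gives_empty_mask(self):
        m = hb.extract_optimal(_surface([0.1, 0.2]))
        assert m.cells == frozenset()

    def test_zero_threshold_takes_all_positive_in_hull_cells(self):
        m = hb.extract_optimal(_surface([0.1, 0.2, 0.3]), threshold=1e-12)
        assert m.cells == {0, 1, 2}

    def test_out_of_hull_cells_never_included(self):
        m = hb.extract_optimal(_surface([0.9, 0.9], in_hull=[True, False]))
        assert m.cells == {0}

    def test_min_cells_exclusion(self):
        assert hb.extract_optimal(_surface([0.9, 0.1]), min_cells=2) is None


class TestOverlapLevels:
    def test_three_set_worked_example(self):
        # A = {1,2}, B = {2,3}, C = {2}: cell 2 is multi, cells 1 and 3 single
        masks = [
            _mask({1, 2}, species="A"),
            _mask({2, 3}, species="B"),
            _mask({2}, species="C"),
        ]
        levels, inter = hb.overlap_levels(masks)
        by_cell = levels.set_index("cell_id")["level"]
        assert by_cell[1] == "single" and by_cell[3] == "single" and by_cell[2] == "multi"
        counts = inter.set_index("subset")["count"]
        assert counts["A"] == 1 and counts["B"] == 1 and counts["A&B&C"] == 1

    def test_disjoint_masks_all_single(self):
        masks = [_mask({1}, species="A"), _mask({2}, species="B"), _mask({3}, species="C")]
        levels, inter = hb.overlap_levels(masks)
        assert (levels["level"] == "single").all()
        assert (inter["n_species"] == 1).all()

    def test_identical_masks_all_pair(self):
        masks = [_mask({1, 2}, species="A"), _mask({1, 2}, species="B")]
        levels, _ = hb.overlap_levels(masks)
        assert (levels["level"] == "pair").all()

    def test_subset_counts_partition_occupied_cells(self):
        rng = np.random.default_rng(3)
        masks = [
            _mask(set(rng.choice(100, size=40, replace=False)), species=s)
            for s in "ABCD"
        ]
        levels, inter = hb.overlap_levels(masks)
        union = set().union(*[m.cells for m in masks])
        assert len(levels) == len(union) == inter["count"].sum()

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            hb.overlap_levels([_mask({1}), _mask({2}, grid_id=("other",))])


class TestOverlapIndex:
    @pytest.mark.parametrize(
        "a,expected",
        [
            ({"single": 1.0, "pair": 0.0, "multi": 0.0}, -0.5),
            ({"single": 0.0, "pair": 0.0, "multi": 1.0}, 2.0),
            ({"single": 0.0, "pair": 1.0, "multi": 0.0}, 1.0),
            ({"single": 0.5, "pair": 0.3, "multi": 0.2}, 0.45),
        ],
    )
    def test_worked_examples(self, a, expected):
        assert hb.overlap_index(a) == pytest.approx(expected)

    def test_no_occupied_cells_warns_zero(self):
        with pytest.warns(UserWarning, match="no occupied"):
            assert hb.overlap_index({"single": 0.0, "pair": 0.0, "multi": 0.0}) == 0.0

    def test_nonunit_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            hb.overlap_index({"single": 0.5, "pair": 0.2, "multi": 0.2})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bounds_property(self, u, v):
        s = u
        p = (1 - u) * v
        m = 1 - s - p
        idx = hb.overlap_index({"single": s, "pair": p, "multi": max(m, 0.0)})
        assert -0.5 - 1e-9 <= idx <= 2.0 + 1e-9

    def test_monotone_under_mass_shift_to_higher_level(self):
        lo = hb.overlap_index({"single": 0.6, "pair": 0.3, "multi": 0.1})
        hi = hb.overlap_index({"single": 0.5, "pair": 0.3, "multi": 0.2})
        assert hi > lo


class TestSummaryAndReport:
    def test_summary_fields_consistent(self):
        masks = [
            _mask({1, 2, 5}, species="A"),
            _mask({2, 3, 5}, species="B"),
            _mask({5}, species="C"),
        ]
        s = hb.summarize_overlap(masks)
        assert s.count_area == 4  # cells 1, 2, 3, 5
        assert sum(s.a.values()) == pytest.approx(1.0)
        assert s.index == pytest.approx(
            sum(DEFAULT_LEVEL_WEIGHTS[lv] * s.a[lv] for lv in s.a)
        )

    def test_report_sorted_by_index_matches_published_ordering(self):
        # indices mirroring the published seasonal table must come out
        # spring < summer < autumn < winter
        sums = []
        for season, idx in [("winter", 0.5187), ("spring", -0.1583),
                            ("autumn", 0.4612), ("summer", 0.1287)]:
            sums.append(
                hb.OverlapSummary(
                    season=season,
                    level_counts={"single": 1, "pair": 0, "multi": 0},
                    a={"single": 1.0, "pair": 0.0, "multi": 0.0},
                    count_area=1,
                    index=idx,
                )
            )
        rep = hb.seasonal_report(sums)
        assert list(rep["season"]) == ["spring", "summer", "autumn", "winter"]

    def test_single_season_report(self):
        s = hb.summarize_overlap([_mask({1}, species="A", season="summer")])
        rep = hb.seasonal_report([s])
        assert len(rep) == 1 and rep["season"][0] == "summer"

    def test_equal_indices_keep_input_order(self):
        a = hb.summarize_overlap([_mask({1}, species="A", season="summer")])
        b = hb.summarize_overlap([_mask({2}, species="B", season="winter")])
        rep = hb.seasonal_report([a, b])
        assert list(rep["season"]) == ["summer", "winter"]
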