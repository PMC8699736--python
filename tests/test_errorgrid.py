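"""Harm grid construction, zone derivation and point classification."""

import numpy as np
import pytest

from svagree.errorgrid import (
    DEFAULT_PCT_THRESHOLDS,
    HarmGrid,
    HarmWeights,
    ZoneSet,
    build_harm_grid,
    classify_points,
    derive_zones,
    zone_summary,
)
from svagree.simulate import HARM_CATEGORIES, QuestionnaireReturn
from svagree.trend import DeltaPair

from conftest import GRID, uniform_returns


def dp(dref, ddev):
    return DeltaPair("s", "no_tourniquet", 1, dref, ddev)


class TestHarmWeights:
    def test_defaults(self):
        w = HarmWeights()
        assert (w.none, w.mild, w.moderate, w.severe) == (0, 2, 5, 10)

    @pytest.mark.parametrize(
        "kwargs",
        [{"none": 1.0}, {"mild": 0.0}, {"moderate": 11.0}, {"severe": 4.0}],
    )
    def test_non_monotone_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HarmWeights(**kwargs)


class TestHarmGrid:
    def test_unanimous_severe_cell_reaches_max(self, fifteen_identical_returns):
        """15 respondents all rating severe give a raw score of 150."""
        grid = build_harm_grid(fifteen_identical_returns)
        i = grid.grid_steps.index(50.0)
        j = grid.grid_steps.index(0.0)
        assert grid.max_score == 150.0
        assert grid.raw[i, j] == 150.0
        assert grid.pct[i, j] == 100.0

    def test_all_none_scores_zero(self):
        rets = uniform_returns(7)
        grid = build_harm_grid(rets)
        diag = np.diag(grid.raw)
        assert (diag == 0).all()
        # same-category off-diagonal cells also score zero
        i = grid.grid_steps.index(0.0)
        j = grid.grid_steps.index(10.0)
        assert grid.raw[i, j] == 0.0

    def test_mixed_ratings_hand_sum(self):
        """5 none + 5 mild + 5 severe at one cell: raw 60, pct 40."""
        n = len(GRID)

        def uniform_rating(cat):
            return tuple(
                tuple("none" if i == j else cat for j in range(n)) for i in range(n)
            )

        rets = (
            [QuestionnaireReturn(f"a{k}", GRID, uniform_rating("none")) for k in range(5)]
            + [QuestionnaireReturn(f"b{k}", GRID, uniform_rating("mild")) for k in range(5)]
            + [QuestionnaireReturn(f"c{k}", GRID, uniform_rating("severe")) for k in range(5)]
        )
        grid = build_harm_grid(rets)
        assert grid.raw[1, 0] == pytest.approx(60.0)
        assert grid.pct[1, 0] == pytest.approx(40.0)

    def test_mismatched_grids_rejected(self):
        a = uniform_returns(1, grid=GRID)[0]
        b = uniform_returns(1, grid=(0.0, 15.0, 30.0, 45.0, 60.0))[0]
        with pytest.raises(ValueError):
            build_harm_grid([a, b])

    def test_upgrade_monotonicity(self):
        """Upgrading one respondent's rating never lowers a cell score."""
        rets = uniform_returns(3)
        base = build_harm_grid(rets)
        ratings = [list(row) for row in rets[0].ratings]
        i, j = 2, 1  # actual 20% vs measured 10%: mild under (20, 40) thresholds
        assert ratings[i][j] == "mild"
        ratings[i][j] = "severe"
        upgraded = QuestionnaireReturn(rets[0].respondent_id, rets[0].grid_steps,
                                       tuple(tuple(r) for r in ratings))
        new = build_harm_grid([upgraded] + rets[1:])
        assert (new.raw >= base.raw).all()

    def test_grid_not_symmetrised(self, fifteen_identical_returns):
        """Over- and under-estimation harm differently; the grid must keep
        that asymmetry (e.g. actual 50 / measured 30 is moderate, while
        30/50 is mild)."""
        grid = build_harm_grid(fifteen_identical_returns)
        i = grid.grid_steps.index(50.0)
        j = grid.grid_steps.index(30.0)
        assert grid.raw[i, j] != grid.raw[j, i]


class TestZones:
    def test_all_zero_grid_single_none_zone(self):
        rets = uniform_returns(3)
        n = len(GRID)
        grid = HarmGrid(GRID, np.zeros((n, n)), n_respondents=3)
        zones = derive_zones(grid)
        assert zones.provenance == "derived_from_grid"
        assert zones.zones["none"].area == pytest.approx(60.0 * 60.0)
        for cat in ("mild", "moderate", "severe"):
            assert zones.zones[cat].is_empty

    def test_two_by_two_banding(self):
        """pct {0, 15; 50, 90} with thresholds (10, 35, 75) bands one cell
        into each zone."""
        steps = (0.0, 10.0)
        raw = np.array([[0.0, 1.5], [5.0, 9.0]])  # pct 0,15,50,90 with 1 respondent
        grid = HarmGrid(steps, raw, n_respondents=1)
        zones = derive_zones(grid, pct_thresholds=(10.0, 35.0, 75.0))
        for cat in HARM_CATEGORIES:
            assert zones.zones[cat].area == pytest.approx(25.0)  # one 5x5 cell
        assert zones.classify(0.0, 0.0) == "none"
        assert zones.classify(1.0, 9.0) == "mild"
        assert zones.classify(9.0, 1.0) == "moderate"
        assert zones.classify(9.0, 9.0) == "severe"

    def test_nonmonotone_thresholds_rejected(self):
        rets = uniform_returns(2)
        grid = build_harm_grid(rets)
        with pytest.raises(ValueError):
            derive_zones(grid, pct_thresholds=(35.0, 13.0, 75.0))

    def test_json_round_trip(self, tmp_path):
        grid = build_harm_grid(uniform_returns(15))
        zones = derive_zones(grid)
        path = tmp_path / "zones.json"
        zones.to_json(path)
        loaded = ZoneSet.from_json(path)
        assert loaded.provenance == "loaded_from_file"
        assert loaded.domain == zones.domain
        for cat in HARM_CATEGORIES:
            assert loaded.zones[cat].symmetric_difference(zones.zones[cat]).area < 1e-9

    def test_single_ring_shorthand_load(self, tmp_path):
        payload = """{
          "zones": {"none": [[0,0],[60,0],[60,60],[0,60]], "mild": [],
                    "moderate": [], "severe": []},
          "domain": [0, 60]
        }"""
        zones = ZoneSet.from_json(payload)
        assert zones.classify(30.0, 10.0) == "none"

    def test_incomplete_cover_rejected(self):
        from shapely.geometry import Polygon, box

        zones = {
            "none": box(0, 0, 30, 30),
            "mild": Polygon(),
            "moderate": Polygon(),
            "severe": Polygon(),
        }
        with pytest.raises(ValueError):
            ZoneSet(zones, domain=(0, 60), provenance="derived_from_grid")


class TestClassification:
    def test_identity_diagonal_is_none(self, fifteen_identical_returns):
        """Diagonal points interior to their cells are no-error, hence zone
        none (points exactly on cell corners tie-break to higher harm)."""
        zones = derive_zones(build_harm_grid(fifteen_identical_returns))
        for fall in (0.0, 4.0, 17.0, 33.0, 58.0, 60.0):
            assert zones.classify(fall, fall) == "none"

    def test_boundary_goes_to_higher_harm(self):
        steps = (0.0, 10.0)
        raw = np.array([[0.0, 1.5], [5.0, 9.0]])
        grid = HarmGrid(steps, raw, n_respondents=1)
        zones = derive_zones(grid, pct_thresholds=(10.0, 35.0, 75.0))
        # (5, 2) is the none/moderate edge -> moderate
        assert zones.classify(5.0, 2.0) == "moderate"
        # (2, 5) is the none/mild edge -> mild
        assert zones.classify(2.0, 5.0) == "mild"
        # (8, 5) lies on the moderate/severe edge -> severe
        assert zones.classify(8.0, 5.0) == "severe"
        # the diagonal corner (5, 5) is a zero-error point touching the
        # none cell, so no-error precedence beats the conservative rule
        assert zones.classify(5.0, 5.0) == "none"

    def test_out_of_domain_clamped(self, fifteen_identical_returns):
        zones = derive_zones(build_harm_grid(fifteen_identical_returns))
        assert zones.classify(-20.0, -30.0) == zones.classify(0.0, 0.0)
        assert zones.classify(90.0, 0.0) == zones.classify(60.0, 0.0)

    def test_delta_sign_convention(self, fifteen_identical_returns):
        """Deltas are signed changes; a -50% reference change with a 0%
        device change lands at grid cell (50, 0) - severe for unanimous
        (20, 40) thresholds."""
        zones = derive_zones(build_harm_grid(fifteen_identical_returns))
        [(d, label)] = classify_points([dp(-50.0, 0.0)], zones)
        assert label == "severe"

    def test_cell_lookup_equivalence(self):
        """Polygon classification agrees with direct nearest-cell band lookup
        for points strictly inside cells, over randomised grids."""
        rng = np.random.default_rng(12)
        for trial in range(5):
            n = len(GRID)
            raw = rng.integers(0, 11, size=(n, n)).astype(float)
            np.fill_diagonal(raw, 0.0)
            grid = HarmGrid(GRID, raw, n_respondents=1)
            zones = derive_zones(grid)
            bands = grid.band(DEFAULT_PCT_THRESHOLDS)
            edges = grid.cell_edges()
            for _ in range(200):
                i = rng.integers(0, n)
                j = rng.integers(0, n)
                # strictly interior point of cell (i, j)
                x = rng.uniform(edges[i] + 1e-6, edges[i + 1] - 1e-6)
                y = rng.uniform(edges[j] + 1e-6, edges[j + 1] - 1e-6)
                assert zones.classify(x, y) == HARM_CATEGORIES[bands[i, j]]


class TestZoneSummary:
    def test_published_style_percentages(self):
        labels = ["none"] * 75 + ["mild"] * 18 + ["moderate"] * 22 + ["severe"] * 6
        s = zone_summary(labels)
        assert s.n_points == 121
        assert s.percentages == {"none": 62, "mild": 15, "moderate": 18, "severe": 5}

    def test_combined_severe_rate(self):
        a = ["severe"] * 6 + ["none"] * 115
        b = ["none"] * 113
        s = zone_summary(a, pooled_strands=b)
        assert s.combined_severe_pct == pytest.approx(2.6)

    def test_single_zone(self):
        s = zone_summary(["mild"] * 10)
        assert s.percentages["mild"] == 100
        assert s.percentages["none"] == 0

    def test_counts_sum_and_order_invariance(self):
        rng = np.random.default_rng(3)
        labels = list(rng.choice(HARM_CATEGORIES, size=57))
        a = zone_summary(labels)
        rng.shuffle(labels)
        b = zone_summary(labels)
        assert a.counts == b.counts
        assert sum(a.counts.values()) == a.n_points

    def test_pooling_associative(self):
        rng = np.random.default_rng(4)
        x = list(rng.choice(HARM_CATEGORIES, size=40))
        y = list(rng.choice(HARM_CATEGORIES, size=30))
        assert (
            zone_summary(x, pooled_strands=y).combined_severe_pct
            == zone_summary(y, pooled_strands=x).combined_severe_pct
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zone_summary([])
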