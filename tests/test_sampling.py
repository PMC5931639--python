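"""Tests for staged location sampling and year-priority selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import streetshare as ss
from streetshare.sampling import expand_headings, stabilisation


def straight_link_network(n_links=5, length=3.0):
    links = {
        f"L{i}": np.array([[0.0, float(i)], [length, float(i)]]) for i in range(n_links)
    }
    return ss.StreetNetwork("city", links)


class TestLinkPoints:
    def test_one_point_per_link(self):
        net = straight_link_network(5)
        pts = ss.sample_link_points(net, seed=0)
        assert len(pts) == 5
        assert sorted(pts["link_id"]) == sorted(net.links)
        # each point lies on its own horizontal link
        for _, row in pts.iterrows():
            y_link = float(row["link_id"][1:])
            assert row["y"] == pytest.approx(y_link)
            assert 0.0 <= row["x"] <= 3.0

    def test_positions_uniform_along_link(self):
        net = straight_link_network(1, length=7.0)
        xs = [float(ss.sample_link_points(net, seed=s)["x"].iloc[0]) for s in range(2000)]
        assert stats.kstest(xs, stats.uniform(0, 7).cdf).pvalue > 0.01

    def test_zero_length_link_rejected(self):
        links = {"ok": np.array([[0.0, 0.0], [1.0, 0.0]]),
                 "degenerate": np.array([[2.0, 2.0], [2.0, 2.0]])}
        with pytest.raises(ValueError, match="degenerate"):
            ss.sample_link_points(ss.StreetNetwork("c", links), seed=0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no links"):
            ss.sample_link_points(ss.StreetNetwork("c", {}), seed=0)

    def test_multisegment_polyline(self):
        links = {"poly": np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])}
        pts = ss.sample_link_points(ss.StreetNetwork("c", links), seed=3)
        x, y = pts[["x", "y"]].iloc[0]
        on_first = y == pytest.approx(0.0) and 0 <= x <= 1
        on_second = x == pytest.approx(1.0) and 0 <= y <= 1
        assert on_first or on_second


class TestStage2:
    def test_sample_size_and_distinctness(self):
        pts = pd.DataFrame({"link_id": range(5000), "x": 0.0, "y": 0.0})
        plan = ss.SamplingPlan(stage2_n=2000, target_locations=1000)
        out = ss.stage2_sample(pts, plan, seed=1)
        assert len(out) == 2000
        assert out["link_id"].is_unique

    def test_identity_when_sample_equals_population(self):
        pts = pd.DataFrame({"link_id": range(100), "x": 0.0, "y": 0.0})
        plan = ss.SamplingPlan(stage2_n=100, target_locations=50)
        out = ss.stage2_sample(pts, plan, seed=1)
        assert set(out["link_id"]) == set(range(100))

    def test_deterministic_under_seed(self):
        pts = pd.DataFrame({"link_id": range(500), "x": 0.0, "y": 0.0})
        plan = ss.SamplingPlan(stage2_n=200, target_locations=100)
        a = ss.stage2_sample(pts, plan, seed=9)
        b = ss.stage2_sample(pts, plan, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_shortfall_error_names_the_gap(self):
        pts = pd.DataFrame({"link_id": range(10), "x": 0.0, "y": 0.0})
        plan = ss.SamplingPlan(stage2_n=100, target_locations=50)
        with pytest.raises(ValueError, match="short by 90"):
            ss.stage2_sample(pts, plan, seed=0)


def meta_frame(spec):
    """Build a metadata frame from {year: [location ids]}."""
    rows = [
        {"location_id": loc, "pano_id": f"{loc}_{year}", "year": year, "month": 6}
        for year, locs in spec.items()
        for loc in locs
    ]
    return pd.DataFrame(rows)


class TestSelectByYear:
    def test_priority_year_taken_in_full_before_filler(self):
        meta = meta_frame({2011: range(600), 2012: range(1000, 1500)})
        plan = ss.SamplingPlan(stage2_n=2000, target_locations=1000)
        selected, short = ss.select_by_year(meta, plan, seed=0)
        assert not short
        counts = selected["year"].value_counts()
        assert counts[2011] == 600
        assert counts[2012] == 400

    def test_earlier_priority_exhausted_before_later(self):
        meta = meta_frame({2009: range(30), 2008: range(100, 140)})
        plan = ss.SamplingPlan(stage2_n=60, target_locations=50)
        selected, short = ss.select_by_year(meta, plan, seed=0)
        counts = selected["year"].value_counts()
        assert counts[2009] == 30  # all of 2009 before any 2008
        assert counts[2008] == 20

    def test_no_location_repeated(self):
        # locations offering both years must be chosen once only
        meta = meta_frame({2011: range(50), 2012: range(25, 75)})
        plan = ss.SamplingPlan(stage2_n=80, target_locations=60)
        selected, _ = ss.select_by_year(meta, plan, seed=0)
        assert selected["location_id"].is_unique
        assert selected["pano_id"].is_unique

    def test_shortfall_returns_all_with_flag(self):
        meta = meta_frame({2011: range(10)})
        plan = ss.SamplingPlan(stage2_n=100, target_locations=50)
        selected, short = ss.select_by_year(meta, plan, seed=0)
        assert short
        assert len(selected) == 10

    def test_year_priority_dominance_invariant(self):
        # no chosen rank-k location may coexist with an unchosen better rank
        rng = np.random.default_rng(0)
        plan = ss.SamplingPlan(stage2_n=200, target_locations=60)
        for trial in range(25):
            spec = {
                year: list(
                    rng.choice(300, size=rng.integers(5, 80), replace=False)
                    + 1000 * i  # disjoint location pools per year
                )
                for i, year in enumerate(plan.year_priority)
            }
            meta = meta_frame(spec)
            selected, _ = ss.select_by_year(meta, plan, seed=trial)
            counts = selected["year"].value_counts()
            ranks = list(plan.year_priority)
            for k, year in enumerate(ranks[:-1]):
                available = len(spec[year])
                if counts.get(ranks[k + 1], 0) > 0:
                    assert counts.get(year, 0) == available

    def test_study_year_mix_ordering(self, small_world):
        # aggregated across cities: 2012 > 2011 > 2009 > 2008 > 2010
        counts = small_world.selected["year"].value_counts()
        assert (
            counts[2012] > counts[2011] > counts[2009] > counts[2008] > counts[2010]
        )


class TestHeadings:
    def test_two_opposite_images_per_location(self):
        meta = meta_frame({2011: range(5)})
        plan = ss.SamplingPlan(stage2_n=5, target_locations=5)
        selected, _ = ss.select_by_year(meta, plan, seed=0)
        images = expand_headings(selected, plan)
        assert len(images) == 10
        per_loc = images.groupby("location_id")["heading"].agg(sorted)
        assert all(h == [0, 180] for h in per_loc)

    def test_plan_validation(self):
        with pytest.raises(ValueError, match="180"):
            ss.SamplingPlan(headings=(0, 90))
        with pytest.raises(ValueError, match="duplicates"):
            ss.SamplingPlan(year_priority=(2011, 2011))
        with pytest.raises(ValueError, match="stage2_n"):
            ss.SamplingPlan(stage2_n=10, target_locations=20)


class TestStabilisation:
    def test_constant_stream_stabilises_at_window(self):
        presence = pd.DataFrame({"cyclist": [True] * 300})
        curve = stabilisation(presence, window=100, tol=0.005)
        assert curve.stabilised_at == 100
        assert np.allclose(curve.proportions["cyclist"], 1.0)

    def test_alternating_stream_matches_naive_scan(self):
        presence = pd.DataFrame({"cyclist": [i % 2 == 0 for i in range(2000)]})
        window, tol = 100, 0.005
        curve = stabilisation(presence, window=window, tol=tol)
        running = np.cumsum(presence["cyclist"].to_numpy()) / np.arange(1, 2001)
        expected = None
        for i in range(window - 1, 2000):
            w = running[i - window + 1 : i + 1]
            if w.max() - w.min() < tol:
                expected = i + 1
                break
        assert curve.stabilised_at == expected
        assert curve.proportions["cyclist"].iloc[-1] == pytest.approx(0.5, abs=1e-3)

    def test_never_stabilising_stream(self):
        presence = pd.DataFrame({"cyclist": ([True] * 50 + [False] * 50) * 3})
        curve = stabilisation(presence, window=100, tol=0.001)
        assert curve.stabilised_at is None

    def test_study_rates_stabilise_quickly(self, small_world):
        # city streams at study-like presence rates settle within ~1200 images
        ann = small_world.annotations
        for city, grp in list(ann.groupby("city_id"))[:3]:
            presence = pd.DataFrame(
                {m: (grp[m] != "0").to_numpy() for m in ["pedestrian", "cyclist", "car"]}
            )
            curve = stabilisation(presence, window=100, tol=0.02)
            assert curve.stabilised_at is not None
            assert curve.stabilised_at <= len(presence)

    def test_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            stabilisation(pd.DataFrame({"m": [True, False]}), window=1)
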