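"""Landmark trait extraction: geometry, scaling and invariances."""

import numpy as np
import pandas as pd
import pytest

from coraldelim.landmarks import LandmarkSet, calibrate, read_landmarks, landmarks_to_frame
from coraldelim.traits import (
    ALL_TRAITS,
    LINEAR_TRAITS,
    MEASURED_TRAITS,
    area_traits,
    derived_traits,
    extract_traits,
    linear_traits,
    polygon_area,
    specimen_summary,
    trait_table,
)
from conftest import make_lm, rigid_motion, ring_template


class TestCalibrate:
    def test_reference_line(self):
        assert calibrate(16.0, 0.16) == pytest.approx(0.01)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            calibrate(0.0)

    def test_roundtrip_square(self):
        # a 100 px square under the derived scale is 1 mm on a side
        scale = calibrate(100.0, 1.0)
        pts = dict(ring_template())
        pts[1], pts[2] = (0.0, 0.0), (0.0, 100.0)
        lm = make_lm(pts, scale=scale)
        assert linear_traits(lm)["SL1"] == pytest.approx(1.0)


class TestLinearTraits:
    def test_three_four_five(self):
        pts = dict(ring_template())
        pts[1], pts[2] = (0.0, 0.0), (3.0, 4.0)
        lm = make_lm(pts, scale=1.0)
        assert linear_traits(lm)["SL1"] == pytest.approx(5.0)

    def test_regular_rings_uniform_and_match_bruteforce(self, ring_lm):
        tv = linear_traits(ring_lm)
        sl = [tv[f"SL{k}"] for k in range(1, 13)]
        sd = [tv[f"SD{k}"] for k in range(1, 13)]
        pd_ = [tv[f"PD{k}"] for k in range(1, 13)]
        assert np.allclose(sl, sl[0]) and np.allclose(sd, sd[0]) and np.allclose(pd_, pd_[0])
        # independent per-pair recomputation
        from coraldelim.traits import _PAIRS  # the catalogue itself

        for name, (i, j) in _PAIRS.items():
            a = np.asarray(ring_lm.points[i])
            b = np.asarray(ring_lm.points[j])
            assert tv[name] == pytest.approx(float(np.hypot(*(a - b))), abs=1e-12)

    def test_emits_42_linear_values(self, ring_lm):
        tv = linear_traits(ring_lm)
        assert len(tv) == 42 and len(LINEAR_TRAITS) == 42
        assert all(np.isfinite(v) for v in tv.values())


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0

    def test_collinear_zero(self):
        assert polygon_area([(0, 0), (1, 1), (2, 2)]) == 0.0

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            polygon_area([(0, 0), (1, 1)])

    def test_matches_fan_triangulation(self):
        rng = np.random.default_rng(4)
        # irregular convex 12-gon (sorted angles keep it simple)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(0.5, 2.0, 12)
        pts = np.c_[rad * np.cos(ang), rad * np.sin(ang)]
        # star-shaped about the origin: fan triangulation from the origin
        tri = 0.0
        for k in range(12):
            b, c = pts[k], pts[(k + 1) % 12]
            tri += abs(float(np.cross(b, c))) / 2
        assert polygon_area(pts) == pytest.approx(tri, abs=1e-12)


class TestAreas:
    def test_inner_ring_smaller(self, ring_lm):
        at = area_traits(ring_lm)
        assert at["FA"] < at["CA"]

    def test_similar_polygon_ratio(self, ring_lm):
        # concentric regular rings radius 1 and 2: area ratio 0.25
        at = area_traits(ring_lm)
        assert at["FA"] / at["CA"] == pytest.approx(0.25, abs=1e-12)

    def test_faca_propagates(self, ring_lm):
        full = extract_traits(ring_lm)
        assert full["FACA"] == pytest.approx(full["FA"] / full["CA"], abs=1e-15)


def septa_lengths_lm(lengths):
    """Custom landmark set whose SL_k equal ``lengths`` exactly."""
    pts = {}
    for k, L in enumerate(lengths, start=1):
        pts[2 * k - 1] = (3.0 * k, 0.0)
        pts[2 * k] = (3.0 * k, float(L))
    pts.update({25: (0, 0), 26: (0, 1), 27: (1, 0), 28: (1, 1)})
    return make_lm(pts, scale=1.0)


class TestDerived:
    def test_irr_zero_for_equal_septa(self, ring_lm):
        assert extract_traits(ring_lm)["IRR"] == pytest.approx(0.0, abs=1e-12)

    def test_irr_circular_hand_value(self):
        lm = septa_lengths_lm([2] + [1] * 11)
        tv = linear_traits(lm)
        tv.update(area_traits(lm))
        d = derived_traits(tv, lm)
        # |2-1| + 10 zeros + |1-2| around the ring
        assert d["IRR"] == pytest.approx(2.0, abs=1e-12)

    def test_irr_all_pairs_mode(self):
        lm = septa_lengths_lm([2] + [1] * 11)
        tv = linear_traits(lm)
        tv.update(area_traits(lm))
        d = derived_traits(tv, lm, irr_mode="all_pairs")
        assert d["IRR"] == pytest.approx(11.0, abs=1e-12)  # 11 pairs differ by 1

    def test_x6_definitional_ratio(self):
        pts = dict(ring_template())
        # make d(1,2) equal the calyx length d(1,13)
        L = float(np.hypot(*(np.asarray(pts[1]) - np.asarray(pts[13]))))
        pts[2] = (pts[1][0], pts[1][1] + L)
        lm = make_lm(pts, scale=1.0)
        assert extract_traits(lm)["X6"] == pytest.approx(1.0, abs=1e-12)

    def test_averages(self, ring_lm):
        full = extract_traits(ring_lm)
        assert full["ASL"] == pytest.approx(
            np.mean([full[f"SL{k}"] for k in range(1, 13)]), abs=1e-12
        )
        assert full["ASW"] == pytest.approx((full["SW1"] + full["SW2"]) / 2, abs=1e-12)


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = ring_template()
        lm = make_lm(pts)
        base = extract_traits(lm)
        moved = rigid_motion(pts, rng.uniform(0, 2 * np.pi), rng.uniform(-5, 5, 2))
        after = extract_traits(make_lm(moved))
        num = base.drop("TRI").astype(float)
        assert np.allclose(after.drop("TRI").astype(float), num, rtol=1e-9, atol=1e-12)

    def test_scale_reciprocal_invariance(self):
        pts = ring_template()
        scaled = {i: (p[0] * 40.0, p[1] * 40.0) for i, p in pts.items()}
        a = extract_traits(make_lm(pts, scale=1.0))
        b = extract_traits(make_lm(scaled, scale=1.0 / 40.0))
        assert np.allclose(a.drop("TRI").astype(float), b.drop("TRI").astype(float), atol=1e-9)

    def test_order_independence(self):
        lms = [make_lm(ring_template(), cid=f"c{i}") for i in range(3)]
        t1 = trait_table(lms)
        t2 = trait_table(lms[::-1])
        assert np.allclose(
            t1.drop(columns=["specimen_id", "region", "species"]).to_numpy(float),
            t2.iloc[::-1].drop(columns=["specimen_id", "region", "species"]).to_numpy(float),
        )

    def test_full_catalogue_counts(self, ring_lm):
        assert len(MEASURED_TRAITS) == 47  # 42 linear + 2 areas + 3 discrete
        full = extract_traits(ring_lm)
        assert list(full.index) == list(ALL_TRAITS)
        assert full[list(MEASURED_TRAITS)].notna().all()


class TestSpecimenSummary:
    def test_single_corallite(self):
        lm = make_lm(ring_template())
        s = specimen_summary(trait_table([lm]))
        row = s[s["trait"] == "ASL"].iloc[0]
        assert row["n_corallites"] == 1 and np.isnan(row["sd"])

    def test_two_corallite_mean(self):
        a = septa_lengths_lm([1.0] * 12)
        b = septa_lengths_lm([3.0] * 12)
        b.corallite_id = "c2"
        s = specimen_summary(trait_table([a, b]))
        assert s[s["trait"] == "ASL"].iloc[0]["mean"] == pytest.approx(2.0)


class TestIO:
    def test_roundtrip(self, tmp_path):
        lms = [make_lm(ring_template(), cid=f"c{i}") for i in range(2)]
        p = tmp_path / "lm.csv"
        landmarks_to_frame(lms).to_csv(p, index=False)
        back = read_landmarks(p)
        assert [x.corallite_id for x in back] == ["c0", "c1"]
        assert np.allclose(
            extract_traits(back[0]).drop("TRI").astype(float),
            extract_traits(lms[0]).drop("TRI").astype(float),
        )

    def test_missing_point_rejected(self):
        pts = ring_template()
        del pts[5]
        with pytest.raises(ValueError, match="missing landmark"):
            make_lm(pts)

    def test_duplicate_point_rejected(self, tmp_path):
        df = landmarks_to_frame([make_lm(ring_template())])
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        p = tmp_path / "dup.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_landmarks(p)

    def test_missing_scale_mentions_calibrate(self, tmp_path):
        df = landmarks_to_frame([make_lm(ring_template())])
        df["scale_mm_per_px"] = np.nan
        p = tmp_path / "noscale.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="calibrate"):
            read_landmarks(p)

    def test_point_29_accepted_and_ignored(self):
        pts = dict(ring_template())
        pts[29] = (99.0, 99.0)
        lm = make_lm(pts)
        base = extract_traits(make_lm(ring_template()))
        assert np.allclose(
            extract_traits(lm).drop("TRI").astype(float), base.drop("TRI").astype(float)
        )
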