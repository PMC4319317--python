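"""Mantel matrix correlation, regression and the per-trait screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import coraldelim.mantel as cm
from coraldelim.mantel import (
    MantelTest,
    genetic_region_matrix,
    mantel_test,
    morph_region_matrix,
    regress_matrices,
    screen_traits,
)
from coraldelim.seqdist import DistanceMatrix, GroupDistanceSummary


def random_dm(n, rng, labels=None):
    m = np.abs(rng.normal(1, 0.4, size=(n, n)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(labels or [f"r{i}" for i in range(n)], m)


def oracle_exhaustive_p(m1, m2, alternative="greater"):
    """Independent enumeration of all n! relabellings of m2."""
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = m1[iu]
    r_obs = scipy.stats.pearsonr(x, m2[iu]).statistic
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        r = scipy.stats.pearsonr(x, m2[np.ix_(p, p)][iu]).statistic
        total += 1
        if alternative == "greater" and r >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / total


class TestMantel:
    def test_matrix_vs_itself(self):
        dm = random_dm(5, np.random.default_rng(0))
        res = mantel_test(dm, dm)
        assert res.r == pytest.approx(1.0)
        assert res.method == "exhaustive"
        assert res.p_value <= 2 / 120  # the smallest attainable neighbourhood

    def test_exhaustive_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        m1, m2 = random_dm(4, rng), random_dm(4, rng)
        res = mantel_test(m1, m2)
        r_oracle, p_oracle = oracle_exhaustive_p(m1.values, m2.values)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 24

    def test_monte_carlo_matches_exhaustive(self, monkeypatch):
        rng = np.random.default_rng(2)
        m1, m2 = random_dm(4, rng), random_dm(4, rng)
        _, p_exact = oracle_exhaustive_p(m1.values, m2.values)
        monkeypatch.setattr(cm, "EXHAUSTIVE_LIMIT", 1)  # force Monte Carlo
        res = mantel_test(m1, m2, n_perm=3000, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 3000)
        assert res.method == "monte-carlo"
        assert res.p_value == pytest.approx(p_exact, abs=max(3 * se, 2 / 3000))

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        m1, m2 = random_dm(5, rng), random_dm(5, rng)
        a = mantel_test(m1, m2)
        b = mantel_test(m2, m1)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)  # both exhaustive

    def test_constant_matrix_flagged(self):
        rng = np.random.default_rng(4)
        m1 = random_dm(4, rng)
        const = DistanceMatrix(m1.labels, np.ones((4, 4)) - np.eye(4))
        with pytest.warns(UserWarning, match="constant"):
            res = mantel_test(m1, const)
        assert res.constant and np.isnan(res.r)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        m1, m2 = random_dm(5, rng), random_dm(5, rng)
        base = mantel_test(m1, m2)
        shifted = m2.values + 0.7
        np.fill_diagonal(shifted, 0)
        res_shift = mantel_test(m1, DistanceMatrix(m2.labels, shifted))
        res_scale = mantel_test(m1, DistanceMatrix(m2.labels, m2.values * 4.2))
        assert res_shift.r == pytest.approx(base.r, abs=1e-12)
        assert res_scale.r == pytest.approx(base.r, abs=1e-12)
        assert res_scale.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_agrees_with_reference_implementation(self):
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel as sk_mantel

        rng = np.random.default_rng(6)
        m1, m2 = random_dm(8, rng), random_dm(8, rng)
        ours = mantel_test(m1, m2, n_perm=99, seed=0)
        ref_r, _, _ = sk_mantel(
            SkDM(m1.values, ids=m1.labels), SkDM(m2.values, ids=m2.labels),
            permutations=0,
        )
        assert ours.r == pytest.approx(ref_r, abs=1e-12)

    def test_null_p_uniform(self):
        """Independent random matrices give uniform Mantel p (KS check)."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            m1, m2 = random_dm(10, rng), random_dm(10, rng)
            ps.append(mantel_test(m1, m2, n_perm=199, seed=int(rng.integers(2**31))).p_value)
        stat = scipy.stats.kstest(ps, "uniform").pvalue
        assert stat > 0.01

    def test_mismatched_labels_rejected(self):
        rng = np.random.default_rng(8)
        m1 = random_dm(4, rng)
        m2 = random_dm(4, rng, labels=["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError):
            MantelTest(m1, m2)


class TestRegression:
    def test_perfectly_linear(self):
        rng = np.random.default_rng(9)
        m1 = random_dm(5, rng)
        m2 = DistanceMatrix(m1.labels, 2.0 * m1.values)
        slope, intercept, r2 = regress_matrices(m1, m2)
        assert slope == pytest.approx(2.0, abs=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_correlation_fixture(self):
        # constructed so the centred pair vectors are exactly orthogonal
        def sym(vals):  # pair order (0,1) (0,2) (0,3) (1,2) (1,3) (2,3)
            m = np.zeros((4, 4))
            m[np.triu_indices(4, k=1)] = vals
            return m + m.T

        a = sym([1, 2, 3, 4, 5, 6])
        b = sym([2, 0, 1, 1, 0, 2])
        labels = list("wxyz")
        _, _, r2 = regress_matrices(DistanceMatrix(labels, a), DistanceMatrix(labels, b))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_equals_mantel_r_squared(self):
        rng = np.random.default_rng(10)
        m1, m2 = random_dm(6, rng), random_dm(6, rng)
        _, _, r2 = regress_matrices(m1, m2)
        assert r2 == pytest.approx(mantel_test(m1, m2).r_squared, abs=1e-12)


def summaries_frame(region_means: dict, traits: list[str], scale=1.0):
    rows = []
    for t in traits:
        for r, v in region_means.items():
            rows.append(
                {"specimen_id": f"{r}-s1", "region": r, "species": "P. lobata",
                 "trait": t, "mean": v * scale, "sd": 0.0, "n_corallites": 10}
            )
    return pd.DataFrame(rows)


class TestRegionMatrices:
    def test_genetic_two_regions(self):
        s = GroupDistanceSummary(
            ["A", "B"], {"A": 0.01, "B": 0.02}, {"A": 0.001, "B": 0.001},
            np.array([[0.01, 0.05], [0.05, 0.02]]), np.zeros((2, 2)),
        )
        gm = genetic_region_matrix(s)
        assert gm.values[0, 1] == pytest.approx(0.05)
        assert gm.values[0, 0] == 0.0

    def test_genetic_order_equivariance(self):
        s = GroupDistanceSummary(
            ["A", "B", "C"], {g: 0.01 for g in "ABC"}, {g: 0.0 for g in "ABC"},
            np.array([[0.01, 0.03, 0.05], [0.03, 0.01, 0.07], [0.05, 0.07, 0.01]]),
            np.zeros((3, 3)),
        )
        g1 = genetic_region_matrix(s, ["A", "B", "C"])
        g2 = genetic_region_matrix(s, ["C", "A", "B"])
        perm = [2, 0, 1]
        assert np.allclose(g2.values, g1.values[np.ix_(perm, perm)])

    def test_morph_mean_differences(self):
        df = summaries_frame({"A": 1.0, "B": 3.0, "C": 6.0}, ["W"])
        mm = morph_region_matrix(df, "W", ["A", "B", "C"])
        assert mm.values[0, 1] == pytest.approx(2.0)
        assert mm.values[1, 2] == pytest.approx(3.0)
        assert mm.values[0, 2] == pytest.approx(5.0)

    def test_morph_equal_means_zero(self):
        df = summaries_frame({"A": 2.0, "B": 2.0, "C": 2.0}, ["W"])
        assert np.all(morph_region_matrix(df, "W").values == 0)

    def test_missing_trait_in_region(self):
        df = summaries_frame({"A": 1.0, "B": 2.0}, ["W"])
        with pytest.raises(ValueError, match="absent"):
            morph_region_matrix(df, "W", ["A", "B", "C"])


class TestScreen:
    def genetic_line(self, positions):
        labels = sorted(positions)
        k = len(labels)
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                m[i, j] = abs(positions[labels[i]] - positions[labels[j]])
        return DistanceMatrix(labels, m)

    def test_planted_trait_tops_ranking(self):
        pos = {"A": 0.0, "B": 0.01, "C": 0.05, "D": 0.09, "E": 0.2}
        gm = self.genetic_line(pos)
        rng = np.random.default_rng(11)
        region_noise = {r: rng.normal() for r in pos}
        df = pd.concat(
            [
                summaries_frame({r: 100 * pos[r] for r in pos}, ["coupled"]),
                summaries_frame(region_noise, ["uncoupled"]),
            ]
        )
        out = screen_traits(gm, df, ["coupled", "uncoupled"], seed=1)
        assert out.iloc[0]["trait"] == "coupled"
        assert out.iloc[0]["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert bool(out.iloc[0]["significant"])

    def test_ranking_unit_invariant(self):
        pos = {"A": 0.0, "B": 0.02, "C": 0.07, "D": 0.11}
        gm = self.genetic_line(pos)
        rng = np.random.default_rng(12)
        means1 = {r: rng.normal() for r in pos}
        means2 = {r: rng.normal() for r in pos}
        df_a = pd.concat([summaries_frame(means1, ["t1"]), summaries_frame(means2, ["t2"])])
        df_b = pd.concat(
            [summaries_frame(means1, ["t1"], scale=1000.0), summaries_frame(means2, ["t2"])]
        )
        out_a = screen_traits(gm, df_a, ["t1", "t2"], seed=3)
        out_b = screen_traits(gm, df_b, ["t1", "t2"], seed=3)
        assert list(out_a["trait"]) == list(out_b["trait"])
        assert np.allclose(out_a["r_squared"], out_b["r_squared"], atol=1e-12)

    def test_null_traits_rarely_flagged(self):
        pos = {"A": 0.0, "B": 0.02, "C": 0.07, "D": 0.11, "E": 0.15}
        gm = self.genetic_line(pos)
        rng = np.random.default_rng(13)
        traits = [f"n{k}" for k in range(40)]
        df = pd.concat(
            [summaries_frame({r: rng.normal() for r in pos}, [t]) for t in traits]
        )
        out = screen_traits(gm, df, traits, seed=5)
        assert out["significant"].mean() <= 0.2  # near the nominal 5%

    def test_empty_trait_list(self):
        pos = {"A": 0.0, "B": 0.02, "C": 0.07}
        out = screen_traits(self.genetic_line(pos), summaries_frame(pos, ["W"]), [])
        assert out.empty
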