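"""CWM arithmetic, habitat ANOVA against the published summary table,
NMDS geometry, and the centroid permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import traitassembly as ta
from traitassembly.community_composition import (
    centroid_test,
    cwm,
    group_summary,
    kruskal_stress,
    nmds,
    one_way_anova,
)
from traitassembly.datasets import site_cwm_table


class TestCWM:
    def test_single_species_identity(self):
        means = pd.DataFrame({"t": [7.3]}, index=["A"])
        out = cwm(pd.Series({"A": 4}), means, ["A"])
        assert out["t"] == pytest.approx(7.3)

    def test_weighted_formula(self):
        means = pd.DataFrame({"t": [10.0, 20.0]}, index=["A", "B"])
        out = cwm(pd.Series({"A": 3, "B": 1}), means, ["A", "B"])
        assert out["t"] == pytest.approx(12.5)

    def test_renormalization_over_subset(self):
        means = pd.DataFrame({"t": [10.0, 20.0, 99.0]}, index=["A", "B", "C"])
        out = cwm(pd.Series({"A": 3, "B": 1, "C": 100}), means, ["A", "B"])
        assert out["t"] == pytest.approx(12.5)

    def test_empty_subset_rejected(self):
        means = pd.DataFrame({"t": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="empty"):
            cwm(pd.Series({"A": 1}), means, [])

    def test_missing_trait_mean_rejected(self):
        means = pd.DataFrame({"t": [np.nan]}, index=["A"])
        with pytest.raises(ValueError, match="missing trait mean"):
            cwm(pd.Series({"A": 1}), means, ["A"])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        vals=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        seed=st.integers(0, 999),
    )
    def test_bounded_by_species_range(self, vals, seed):
        rng = np.random.default_rng(seed)
        sp = [f"s{i}" for i in range(len(vals))]
        means = pd.DataFrame({"t": vals}, index=sp)
        ab = pd.Series(rng.integers(1, 20, len(vals)), index=sp)
        out = cwm(ab, means, sp)["t"]
        assert min(vals) - 1e-9 <= out <= max(vals) + 1e-9


class TestAnova:
    def test_published_phenols_row(self):
        t = site_cwm_table()
        sef = t.loc[t.habitat == "SEF", "phenols"]
        ogf = t.loc[t.habitat == "OGF", "phenols"]
        F, p = one_way_anova(sef, ogf)
        assert F == pytest.approx(1.02, abs=0.005)
        assert p == pytest.approx(0.35, abs=0.005)

    def test_identical_groups(self):
        F, p = one_way_anova([1.0, 2, 3], [1.0, 2, 3])
        assert F == 0.0 and p == 1.0

    def test_zero_within_variance_unequal_means(self):
        F, p = one_way_anova([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(F) and p == 0.0

    def test_parametric_matches_permutation_reference(self):
        # moderate shift (extreme shifts hit the floor of the exhaustive
        # permutation distribution): F-test p vs exhaustive label shuffles
        rng = np.random.default_rng(8)
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 0.8
        F_obs, p_param = one_way_anova(a, b)
        pooled = np.concatenate([a, b])
        count = total = 0
        for idx in itertools.combinations(range(12), 6):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(12) if i not in idx]]
            F, _ = one_way_anova(ga, gb)
            count += F >= F_obs
            total += 1
        p_perm = count / total
        assert abs(p_param - p_perm) < 0.05

    def test_group_summary_matches_published_cells(self):
        t = site_cwm_table()
        s = group_summary(t["phenols"], t["habitat"])
        assert s.loc["SEF", "mean"] == pytest.approx(54.64, abs=0.005)
        assert s.loc["SEF", "sd"] == pytest.approx(58.20, abs=0.005)
        assert s.loc["OGF", "mean"] == pytest.approx(25.08, abs=0.0051)
        assert s.loc["OGF", "sd"] == pytest.approx(5.37, abs=0.005)


class TestNMDS:
    def test_planar_configuration_near_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 2))
        df = pd.DataFrame(pts, columns=["a", "b"])
        res = nmds(df, k=2, n_restarts=3, seed=1)
        assert res.stress < 0.1  # 0-100 scale

    def test_three_points_always_embed(self):
        df = pd.DataFrame({"a": [0.0, 3.0, 1.0], "b": [0.0, 0.0, 5.0], "c": [1.0, -2.0, 0.5]})
        res = nmds(df, k=2, n_restarts=2, seed=0)
        assert res.stress < 1e-4

    def test_tetrahedron_positive_stable_stress(self):
        # 4 equidistant points cannot embed in the plane
        df = pd.DataFrame(np.eye(4) * np.sqrt(2) / 2)
        r1 = nmds(df, k=2, n_restarts=10, seed=0)
        r2 = nmds(df, k=2, n_restarts=10, seed=99)
        assert r1.stress > 0.5
        assert abs(r1.stress - r2.stress) < 0.1  # 0-100 scale: 1e-3 fractional
        assert np.allclose(
            r1.coordinates[["axis1", "axis2"]].mean(), 0.0, atol=1e-9)

    def test_stress_function_zero_for_perfect_fit(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist
        assert kruskal_stress(pdist(pts), pts) == pytest.approx(0.0, abs=1e-12)


class TestCentroidTest:
    def test_complete_separation(self):
        coords = np.array([[0.0, 0.0]] * 3 + [[10.0, 0.0]] * 3)
        r2, p = centroid_test(coords, ["a"] * 3 + ["b"] * 3, n_perm=999, seed=0)
        assert r2 == pytest.approx(1.0)
        assert p <= 0.11  # only C(6,3)=20 distinct labelings exist

    def test_exhaustive_oracle_six_points(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(6, 2))
        labels = ["a", "a", "a", "b", "b", "b"]
        r2_obs, p_samp = centroid_test(coords, labels, n_perm=9999, seed=1)

        # oracle: every distinct assignment of 3 a's among 6 points
        from traitassembly.community_composition import _centroid_r2
        count = total = 0
        for idx in itertools.combinations(range(6), 3):
            codes = np.array([0 if i in idx else 1 for i in range(6)])
            count += _centroid_r2(coords, codes, 2) >= r2_obs - 1e-12
            total += 1
        p_exh = count / total
        assert abs(p_samp - p_exh) < 0.02

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(400):
            coords = rng.normal(size=(12, 2))
            labels = ["a"] * 6 + ["b"] * 6
            _, p = centroid_test(coords, labels, n_perm=99, seed=rep)
            ps.append(p)
        from scipy.stats import kstest
        # exact null CDF of the add-one p: uniform on {1/100, ..., 1}
        cdf = lambda x: np.floor(np.clip(x, 0, 1) * 100) / 100
        assert kstest(ps, cdf).pvalue > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            centroid_test(np.zeros((3, 2)), ["a", "a", "a"])
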