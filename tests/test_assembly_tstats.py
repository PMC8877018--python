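"""Variance decomposition, T-statistic ratios, null models against
exhaustive enumeration, and the SES/p rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import traitassembly as ta
from traitassembly.assembly_tstats import (
    null_local,
    null_regional_ind,
    null_regional_pop,
    ses_and_p,
    t_statistics,
    variance_components,
)


def _table(site_species_values):
    """site_species_values: list of (site, species, [values])."""
    rows = []
    for site, sp, vals in site_species_values:
        for i, v in enumerate(vals):
            rows.append({"site": site, "habitat": "SEF", "species": sp,
                         "individual": f"{site}_{sp}_{i}", "x": v})
    return ta.TraitTable(pd.DataFrame(rows))


class TestVarianceComponents:
    def test_hand_example(self, two_pop_table):
        c = variance_components(two_pop_table, "x", "c1")
        assert c.sigma2_IP == pytest.approx(2.0)
        assert c.sigma2_IC == pytest.approx(20 / 3)
        assert c.sigma2_PC == pytest.approx(8.0)
        t = t_statistics(c)
        assert t["T_IP_IC"] == pytest.approx(0.3)
        assert t["T_IC_IR"] == pytest.approx(1.0)  # region == community here

    def test_all_identical_zero_components(self):
        t = _table([("c1", "A", [2.0, 2.0]), ("c1", "B", [2.0, 2.0])])
        c = variance_components(t, "x", "c1")
        assert c.sigma2_IP == 0 and c.sigma2_IC == 0 and c.sigma2_PC == 0

    def test_single_population_pc_missing(self):
        t = _table([("c1", "A", [1.0, 2.0, 3.0])])
        c = variance_components(t, "x", "c1")
        assert math.isnan(c.sigma2_PC)
        assert any("single population" in n for n in c.notes)

    def test_no_multi_individual_population_ip_missing(self):
        t = _table([("c1", "A", [1.0]), ("c1", "B", [2.0]), ("c1", "C", [5.0])])
        c = variance_components(t, "x", "c1")
        assert math.isnan(c.sigma2_IP)

    def test_law_of_total_variance_weighted(self):
        rng = np.random.default_rng(7)
        t = _table([("c1", sp, list(rng.normal(size=n)))
                    for sp, n in (("A", 3), ("B", 5), ("C", 2), ("D", 4))])
        c = variance_components(t, "x", "c1")
        assert c.sigma2_IP_weighted + c.sigma2_PC_weighted == pytest.approx(
            c.sigma2_IC, abs=1e-9)

    def test_zero_denominator_gives_missing_ratio(self):
        t = _table([("c1", "A", [2.0, 2.0]), ("c1", "B", [2.0, 2.0]),
                    ("c2", "A", [1.0, 3.0])])
        c = variance_components(t, "x", "c1")
        assert math.isnan(t_statistics(c)["T_IP_IC"])  # sigma2_IC == 0


class TestNullModels:
    def test_local_exhaustive_oracle(self):
        t = _table([("c1", "A", [1.0, 4.0]), ("c1", "B", [6.0, 9.0])])
        vals = np.array([1.0, 4.0, 6.0, 9.0])

        def t_ip_ic(v):
            s_ip = (np.var(v[:2], ddof=1) + np.var(v[2:], ddof=1)) / 2
            return s_ip / np.var(v, ddof=1)

        exhaustive = [t_ip_ic(vals[list(p)]) for p in itertools.permutations(range(4))]
        null = null_local(t, "x", "c1", n_perm=10_000, seed=0)
        se = np.std(exhaustive, ddof=1) / math.sqrt(null.size)
        assert abs(null.mean() - np.mean(exhaustive)) < 6 * se
        assert np.std(null, ddof=1) == pytest.approx(np.std(exhaustive, ddof=1), rel=0.05)

    def test_local_degenerate_values(self):
        t = _table([("c1", "A", [3.0, 3.0]), ("c1", "B", [3.0, 3.0])])
        null = null_local(t, "x", "c1", n_perm=99, seed=0)
        assert np.isnan(null).all()  # sigma2_IC = 0 in every permutation

    def test_local_seed_reproducible(self, two_pop_table):
        a = null_local(two_pop_table, "x", "c1", n_perm=999, seed=5)
        b = null_local(two_pop_table, "x", "c1", n_perm=999, seed=5)
        assert np.array_equal(a, b)

    def test_regional_ind_exhaustive_oracle(self):
        t = _table([("c1", "A", [1.0, 5.0]), ("c1", "B", [2.0]),
                    ("c2", "A", [8.0, 3.0]), ("c2", "B", [7.0])])
        vals = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 7.0])
        s_ir = np.var(vals, ddof=1)
        exhaustive = [np.var(vals[list(p)][:3], ddof=1) / s_ir
                      for p in itertools.permutations(range(6))]
        null = null_regional_ind(t, "x", n_perm=10_000, seed=1)["c1"]
        se = np.std(exhaustive, ddof=1) / math.sqrt(null.size)
        assert abs(null.mean() - np.mean(exhaustive)) < 6 * se
        assert np.std(null, ddof=1) == pytest.approx(np.std(exhaustive, ddof=1), rel=0.05)

    def test_regional_ind_whole_region_is_unit(self):
        t = _table([("c1", "A", [1.0, 5.0]), ("c1", "B", [2.0, 9.0])])
        null = null_regional_ind(t, "x", n_perm=99, seed=0)["c1"]
        assert np.allclose(null, 1.0)

    def test_regional_pop_exhaustive_oracle(self):
        t = _table([("c1", "A", [1.0]), ("c1", "B", [4.0]),
                    ("c2", "A", [6.0]), ("c2", "B", [9.0])])
        pop_means = np.array([1.0, 4.0, 6.0, 9.0])
        s_pr = np.var(pop_means, ddof=1)
        exhaustive = [np.var(pop_means[list(idx)], ddof=1) / s_pr
                      for idx in itertools.combinations(range(4), 2)]
        null = null_regional_pop(t, "x", n_perm=10_000, seed=2)["c1"]
        se = np.std(exhaustive, ddof=1) / math.sqrt(null.size)
        assert abs(null.mean() - np.mean(exhaustive)) < 6 * se

    def test_regional_pop_equal_means_degenerate(self):
        t = _table([("c1", "A", [2.0]), ("c1", "B", [2.0]),
                    ("c2", "A", [2.0]), ("c2", "B", [2.0])])
        null = null_regional_pop(t, "x", n_perm=99, seed=0)["c1"]
        assert np.isnan(null).all() or np.allclose(null[~np.isnan(null)], null[0])


class TestSesAndP:
    def test_obs_at_null_mean_gives_zero(self):
        ses, _ = ses_and_p(2.0, np.array([1.0, 2.0, 3.0]))
        assert ses == 0.0

    def test_hand_example(self):
        ses, _ = ses_and_p(3.0, np.array([1.0, 2.0, 3.0]))
        assert ses == pytest.approx(1.0)  # sample SD = 1

    def test_add_one_boundary(self):
        null = np.linspace(1.0, 2.0, 999)
        _, p = ses_and_p(0.5, null)
        assert p == pytest.approx(2 * 1 / 1000)

    def test_degenerate_null(self):
        ses, p = ses_and_p(1.0, np.ones(99))
        assert math.isnan(ses)
        assert p == 1.0  # all ties


class TestDatasetDriver:
    def test_tidy_output_shape(self, small_dataset):
        res = ta.tstats_for_dataset(small_dataset.traits, columns=["trait1"],
                                    n_perm=99, seed=0)
        assert set(res["statistic"]) == {"T_IP_IC", "T_IC_IR", "T_PC_PR"}
        assert len(res) == 3 * small_dataset.community.data.shape[0]
        valid = res.dropna(subset=["p_value"])
        assert ((valid["p_value"] > 0) & (valid["p_value"] <= 1)).all()

    def test_habitat_contrast_runs(self, small_dataset):
        res = ta.tstats_for_dataset(small_dataset.traits, columns=["trait1"],
                                    n_perm=99, seed=0)
        hab = small_dataset.traits.data.drop_duplicates("site").set_index("site")["habitat"]
        hc = ta.habitat_contrast(res, hab)
        assert set(hc["statistic"]) == {"T_IP_IC", "T_IC_IR", "T_PC_PR"}
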