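"""Fourth-corner and RLQ: brute-force inflated-table oracle, co-inertia
accounting, and the extended decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import traitassembly as ta
from traitassembly.env_association import fourth_corner, phylo_eigenvectors, rlq, extended_rlq


def _toy(seed=0, n_sites=3, n_species=3):
    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(n_sites)]
    species = [f"sp{j}" for j in range(n_species)]
    L = pd.DataFrame(rng.integers(0, 6, (n_sites, n_species)), index=sites, columns=species)
    L.iloc[0, 0] += 1  # ensure positive total
    R = pd.DataFrame({"e1": rng.normal(size=n_sites), "e2": rng.normal(size=n_sites)}, index=sites)
    Q = pd.DataFrame({"t1": rng.normal(size=n_species), "t2": rng.normal(size=n_species)}, index=species)
    return R, L, Q


def _inflated_r(R, L, Q, env, trait):
    """Brute-force oracle: build the one-row-per-individual inflated table
    and take its ordinary Pearson correlation."""
    xs, ys = [], []
    for site in L.index:
        for sp in L.columns:
            for _ in range(int(L.loc[site, sp])):
                xs.append(R.loc[site, env])
                ys.append(Q.loc[sp, trait])
    return np.corrcoef(xs, ys)[0, 1]


class TestFourthCorner:
    def test_identity_linkage_perfect_correlation(self):
        sites = ["s1", "s2", "s3"]
        species = ["a", "b", "c"]
        L = pd.DataFrame(np.eye(3, dtype=int), index=sites, columns=species)
        R = pd.DataFrame({"e": [1.0, 2.0, 5.0]}, index=sites)
        Q = pd.DataFrame({"t": [1.0, 2.0, 5.0]}, index=species)
        res = fourth_corner(R, L, Q, n_perm=99, seed=0)
        assert res.table.loc[0, "r"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_inflated_table_oracle(self, seed):
        R, L, Q = _toy(seed)
        res = fourth_corner(R, L, Q, n_perm=9, seed=0)
        for _, row in res.table.iterrows():
            oracle = _inflated_r(R, L, Q, row["env"], row["trait"])
            assert row["r"] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_scaling_L(self):
        R, L, Q = _toy(4)
        r1 = fourth_corner(R, L, Q, n_perm=9, seed=0).table["r"]
        r2 = fourth_corner(R, L * 7, Q, n_perm=9, seed=0).table["r"]
        assert np.allclose(r1, r2, atol=1e-12)

    def test_constant_env_reported_missing(self):
        R, L, Q = _toy(5)
        R["flat"] = 3.0
        res = fourth_corner(R, L, Q, n_perm=9, seed=0)
        flat = res.table[res.table["env"] == "flat"]
        assert flat["r"].isna().all()
        assert (flat["note"] != "").all()

    def test_null_calibration_shuffled_env(self):
        # environment independent of everything: p should be uniform
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(300):
            R, L, Q = _toy(1000 + rep, n_sites=8, n_species=6)
            res = fourth_corner(R[["e1"]], L, Q[["t1"]], n_perm=99, seed=rep)
            ps.append(res.table.loc[0, "p_value"])
        # two-sided add-one p on a grid: compare against a uniform with
        # generous alpha
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_combined_model_is_max_of_sequential(self):
        R, L, Q = _toy(7, n_sites=6, n_species=5)
        ps = fourth_corner(R, L, Q, model="sites", n_perm=99, seed=1).table["p_value"]
        pq = fourth_corner(R, L, Q, model="species", n_perm=99, seed=1).table["p_value"]
        pc = fourth_corner(R, L, Q, model="combined", n_perm=99, seed=1).table["p_value"]
        assert np.allclose(pc, np.maximum(ps, pq))


class TestRLQ:
    def test_single_pair_single_axis(self):
        R, L, Q = _toy(8, n_sites=5, n_species=4)
        res = rlq(R[["e1"]], L, Q[["t1"]])
        assert len(res.eigenvalues) == 1
        assert res.percent[0] == pytest.approx(100.0)

    def test_eigenvalue_sum_equals_total_coinertia(self):
        R, L, Q = _toy(9, n_sites=6, n_species=5)
        res = rlq(R, L, Q)
        assert res.eigenvalues.sum() == pytest.approx(res.total_coinertia, abs=1e-9)
        # independent recomputation of the weighted cross-product norm
        Lm = L.to_numpy(float)
        P = Lm / Lm.sum()
        r, c = P.sum(1), P.sum(0)
        Rs = (R - r @ R) / np.sqrt(r @ ((R - r @ R) ** 2))
        Qs = (Q - c @ Q) / np.sqrt(c @ ((Q - c @ Q) ** 2))
        M = Rs.to_numpy().T @ (P - np.outer(r, c)) @ Qs.to_numpy()
        assert res.total_coinertia == pytest.approx((M**2).sum(), abs=1e-9)

    def test_duplicate_env_column_keeps_eigenvalues_stable_rank(self):
        R, L, Q = _toy(10, n_sites=6, n_species=5)
        res1 = rlq(R, L, Q)
        R2 = R.copy()
        R2["e1_dup"] = R["e1"]
        res2 = rlq(R2, L, Q)
        # a collinear column adds co-inertia mass but no new structure:
        # rank cannot exceed min(#independent env, #traits)
        assert len(res2.eigenvalues) <= min(2, Q.shape[1])

    def test_loadings_orthonormal(self):
        R, L, Q = _toy(11, n_sites=7, n_species=6)
        res = rlq(R, L, Q)
        for Ldf in (res.env_loadings, res.trait_loadings):
            G = Ldf.to_numpy().T @ Ldf.to_numpy()
            assert np.allclose(G, np.eye(G.shape[0]), atol=1e-9)

    def test_one_species_per_site_reduces_to_paired_coinertia(self):
        # L = identity: sites and species pair one-to-one with equal
        # weights; RLQ equals the co-inertia of the paired tables
        rng = np.random.default_rng(12)
        n = 6
        sites = [f"s{i}" for i in range(n)]
        species = [f"sp{i}" for i in range(n)]
        L = pd.DataFrame(np.eye(n, dtype=int), index=sites, columns=species)
        R = pd.DataFrame({"e1": rng.normal(size=n), "e2": rng.normal(size=n)}, index=sites)
        Q = pd.DataFrame({"t1": rng.normal(size=n), "t2": rng.normal(size=n)}, index=species)
        res = rlq(R, L, Q)
        # oracle: uniform-weight co-inertia, cross-covariance of z-scores
        Rz = (R - R.mean()) / R.std(ddof=0)
        Qz = (Q - Q.mean()) / Q.std(ddof=0)
        M = Rz.to_numpy().T @ Qz.to_numpy() / n
        s = np.linalg.svd(M, compute_uv=False)
        assert np.allclose(np.sort(res.eigenvalues)[::-1], np.sort(s**2)[::-1], atol=1e-9)


class TestExtendedRLQ:
    def test_decomposition_additivity(self, small_dataset):
        stm = ta.species_means(small_dataset.traits)
        q = stm.mean.dropna(how="any")
        res = extended_rlq(small_dataset.env, small_dataset.community, q,
                           small_dataset.phylogeny)
        gap = (res.global_scores - res.trait_based - res.phylogeny_based).abs().max()
        assert gap < 1e-12

    def test_star_tree_no_preferred_phylo_axis(self, star_tree_8):
        # constant patristic distances: the PCoA spectrum is flat, so the
        # encoding carries no discriminating phylogenetic structure
        vecs = phylo_eigenvectors(star_tree_8, star_tree_8.labels, min_representation=0.99)
        G = vecs.to_numpy() @ vecs.to_numpy().T
        vals = np.linalg.eigvalsh(G + 0.0)
        pos = vals[vals > 1e-8]
        assert np.allclose(pos, pos[0], rtol=1e-6)

    def test_tree_coverage_required(self, small_dataset, star_tree_8):
        stm = ta.species_means(small_dataset.traits)
        with pytest.raises(ValueError, match="cover"):
            extended_rlq(small_dataset.env, small_dataset.community,
                         stm.mean.dropna(how="any"), star_tree_8)

    def test_signal_beats_tip_shuffled_control(self):
        # traits with strong phylogenetic signal tracked by the
        # environment: extended RLQ concentrates more co-inertia on axis 1
        # than with a tip-shuffled tree, in most replicates
        wins = ties = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = ta.SimulationConfig(
                n_species=16, n_sites=6, n_individuals_per_site=20,
                lambda_signal=1.0, external_filter_sd=0.5,
                intraspecific_sd=0.2, n_traits=2, seed=5000 + rep)
            ds = ta.generate_dataset(cfg)
            stm = ta.species_means(ds.traits)
            q = stm.mean.dropna(how="any")
            res = extended_rlq(ds.env, ds.community, q, ds.phylogeny)
            # control: same topology, labels shuffled across tips
            import re
            rng = np.random.default_rng(rep)
            labels = list(ds.phylogeny.labels)
            mapping = dict(zip(labels, rng.permutation(labels)))
            newick = re.sub(
                r"([(,])(\w+):",
                lambda m: m.group(1) + mapping[m.group(2)] + ":",
                ds.phylogeny.to_newick(),
            )
            control_tree = ta.Phylogeny.from_newick(newick)
            ctrl = extended_rlq(ds.env, ds.community, q, control_tree)
            if res.percent[0] > ctrl.percent[0]:
                wins += 1
        assert wins >= n_rep // 2
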