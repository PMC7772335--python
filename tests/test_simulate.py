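"""Structured-coalescent simulator: calibration against coalescent theory,
bookkeeping invariants, and the two implementation routes against each
other."""

import numpy as np
import pytest

from demosfs import (
    ScaledParams,
    SimConfig,
    branch_category_lengths,
    build_joint_sfs,
    drop_mutations,
    expected_jsfs,
    hudson_fst,
    make_model_spec,
    simulate_dataset,
    simulate_genealogy,
    simulate_sfs_counts,
)


class TestSingleTreeStructure:
    def test_ultrametric_and_event_count(self, constant_pop, rng):
        spec, params = constant_pop
        g = simulate_genealogy(spec, params, 5, 3, rng)
        assert g.n_leaves == 8 and g.n_nodes == 15
        # leaves at time 0, internal nodes increasing in time
        assert np.all(g.time[:8] == 0)
        assert np.all(np.diff(g.time[8:]) >= 0)
        # every non-root node has a parent later in time
        for v in range(g.n_nodes - 1):
            assert g.time[g.parent[v]] >= g.time[v]

    def test_category_lengths_conserve_total_length(self, asymig_spec,
                                                    asymig_truth, rng):
        for _ in range(25):
            g = simulate_genealogy(asymig_spec, asymig_truth, 2, 2, rng)
            t = branch_category_lengths(g)
            assert t[0, 0] == 0 and t[g.n1, g.n2] == 0
            assert t.sum() == pytest.approx(g.total_branch_length())

    def test_two_leaf_categories(self, constant_pop, rng):
        spec, params = constant_pop
        g = simulate_genealogy(spec, params, 2, 0, rng)
        t = branch_category_lengths(g)
        assert t[1, 0] == pytest.approx(2 * g.tmrca)
        g2 = simulate_genealogy(spec, params, 1, 1, rng)
        t2 = branch_category_lengths(g2)
        assert t2[1, 0] == pytest.approx(g2.tmrca)
        assert t2[0, 1] == pytest.approx(g2.tmrca)

    def test_newick_export_parses(self, constant_pop, rng):
        spec, params = constant_pop
        g = simulate_genealogy(spec, params, 3, 2, rng)
        nwk = g.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == g.n_leaves - 1


class TestCoalescentCalibration:
    def test_mean_pairwise_time_is_one(self, constant_pop, rng):
        spec, params = constant_pop
        times = [
            simulate_genealogy(spec, params, 2, 0, rng).tmrca
            for _ in range(10_000)
        ]
        assert np.mean(times) == pytest.approx(1.0, abs=0.03)

    def test_no_cross_coalescence_before_split_without_migration(self, rng):
        spec = make_model_spec("NOMIG")
        params = ScaledParams(nu_af=1, nu_bot=0.5, nu_eu=1, T_split=0.6,
                              T_exp=1.2)
        for _ in range(300):
            g = simulate_genealogy(spec, params, 3, 3, rng)
            c1, c2 = g.leaf_counts()
            for v in range(g.n_leaves, g.n_nodes):
                a, b = g.children[v]
                mixes = (c1[a] > 0 and c2[b] > 0) or (c2[a] > 0 and c1[b] > 0)
                if g.time[v] < params.T_split:
                    assert not mixes

    def test_two_sample_tmrca_exceeds_split_nomig(self, rng):
        spec = make_model_spec("NOMIG")
        params = ScaledParams(T_split=0.4, T_exp=0.9)
        for _ in range(200):
            g = simulate_genealogy(spec, params, 1, 1, rng)
            assert g.tmrca > params.T_split


class TestMutations:
    def test_zero_theta_gives_no_sites(self, constant_pop, rng):
        spec, params = constant_pop
        g = simulate_genealogy(spec, params, 4, 0, rng)
        assert drop_mutations(g, 0.0, rng) == []

    def test_expected_segregating_sites(self, constant_pop, rng):
        # E[S] = theta * a_{n-1}; a_1 = 1 for n = 2
        spec, params = constant_pop
        s = [
            len(drop_mutations(simulate_genealogy(spec, params, 2, 0, rng),
                               1.0, rng))
            for _ in range(20_000)
        ]
        assert np.mean(s) == pytest.approx(1.0, abs=0.03)

    def test_singleton_inflation_doubles_external_mutations(self, constant_pop):
        spec, params = constant_pop
        rng1 = np.random.default_rng(7)
        trees = [simulate_genealogy(spec, params, 10, 0, rng1)
                 for _ in range(3_000)]

        def singleton_count(f, seed):
            r = np.random.default_rng(seed)
            tot = 0
            for g in trees:
                tot += sum(1 for s in drop_mutations(g, 2.0, r, inflation_f=f)
                           if s.i + s.j == 1)
            return tot

        s1 = singleton_count(1.0, 11)
        s2 = singleton_count(2.0, 11)
        assert s2 / s1 == pytest.approx(2.0, rel=0.1)

    def test_negative_theta_rejected(self, constant_pop, rng):
        spec, params = constant_pop
        g = simulate_genealogy(spec, params, 2, 0, rng)
        with pytest.raises(ValueError):
            drop_mutations(g, -1.0, rng)


class TestExpectedJSFS:
    def test_single_population_closed_form(self, constant_pop):
        # E[xi_i] = theta / i for a constant-size population
        spec, params = constant_pop
        e = expected_jsfs(spec, params, 5, 0, 50_000, 123)
        xi = e.per_theta[1:5, 0]
        np.testing.assert_allclose(xi, 1.0 / np.arange(1, 5), rtol=0.03)

    def test_two_sample_singleton_expectation(self, constant_pop):
        spec, params = constant_pop
        e = expected_jsfs(spec, params, 2, 0, 30_000, 5)
        assert e.per_theta[1, 0] == pytest.approx(1.0, rel=0.03)

    def test_high_migration_approaches_panmixia(self):
        # strong migration: joint SFS -> panmictic SFS split hypergeometrically
        # (two demes of size 1/2 pool to a panmictic population of size 1;
        # the split is placed far older than the TMRCA)
        spec = make_model_spec("SYMIG")
        params = ScaledParams(nu_af=0.5, nu_bot=0.5, nu_eu=0.5, T_split=30.0,
                              T_exp=31.0, M_AtoE=100.0, M_EtoA=100.0)
        n1 = n2 = 2
        e = expected_jsfs(spec, params, n1, n2, 150_000, 17)
        from math import comb

        n = n1 + n2
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                k = i + j
                if k == 0 or k == n:
                    continue
                want = (1.0 / k) * comb(n1, i) * comb(n2, j) * comb(n, k) ** -1
                assert e.per_theta[i, j] == pytest.approx(want, rel=0.05)

    def test_python_and_kernel_routes_agree(self, asymig_spec, asymig_truth):
        rng = np.random.default_rng(31)
        nrep = 4_000
        acc = np.zeros((8, 8))
        acc2 = np.zeros((8, 8))
        for _ in range(nrep):
            t = branch_category_lengths(
                simulate_genealogy(asymig_spec, asymig_truth, 7, 7, rng)
            )
            acc += t
            acc2 += t * t
        py = acc / (2 * nrep)
        se_py = np.sqrt(
            np.maximum(acc2 / nrep - (acc / nrep) ** 2, 0) / nrep
        ) / 2
        ke = expected_jsfs(asymig_spec, asymig_truth, 7, 7, 100_000, 77)
        se = np.sqrt(se_py**2 + ke.se**2) + 1e-12
        z = np.abs(py - ke.per_theta) / se
        sel = ke.per_theta > 0.01
        assert np.max(z[sel]) < 5.0  # both routes are Monte Carlo
        assert py.sum() == pytest.approx(ke.total, rel=0.02)

    def test_deterministic_given_seed(self, asymig_spec, asymig_truth):
        a = expected_jsfs(asymig_spec, asymig_truth, 4, 4, 2_000, 99)
        b = expected_jsfs(asymig_spec, asymig_truth, 4, 4, 2_000, 99)
        np.testing.assert_array_equal(a.per_theta, b.per_theta)


class TestDatasetGenerator:
    def test_empty_dataset_valid(self, asymig_spec, asymig_truth):
        cfg = SimConfig(spec=asymig_spec, params=asymig_truth, n_loci=0, seed=1)
        ds = simulate_dataset(cfg)
        assert ds.n_sites == 0 and ds.n_samples == 28
        assert ds.provenance["seed"] == 1

    def test_shared_polymorphism_present(self, asymig_spec, asymig_truth):
        cfg = SimConfig(spec=asymig_spec, params=asymig_truth, n_loci=500,
                        theta_locus=5.0, seed=3)
        ds = simulate_dataset(cfg)
        j = build_joint_sfs(ds)
        assert j.counts[1:-1, 1:-1].sum() > 0  # segregating in both pops

    def test_determinism(self, asymig_spec, asymig_truth):
        cfg = SimConfig(spec=asymig_spec, params=asymig_truth, n_loci=50,
                        theta_locus=3.0, seed=8)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.rec_rate, b.rec_rate)

    def test_positions_increase_within_locus(self, asymig_spec, asymig_truth):
        cfg = SimConfig(spec=asymig_spec, params=asymig_truth, n_loci=30,
                        theta_locus=5.0, seed=4)
        ds = simulate_dataset(cfg)
        for ctg in set(ds.contig.astype(str)):
            p = ds.pos[ds.contig == ctg]
            assert np.all(np.diff(p) > 0)

    def test_invalid_fractions_rejected(self, asymig_spec, asymig_truth):
        cfg = SimConfig(spec=asymig_spec, params=asymig_truth,
                        recomb_class_fractions=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()


def test_fst_decreases_with_migration():
    """Higher gene flow homogenizes allele frequencies (shared kernel seeds)."""
    fsts = []
    for m in (0.5, 2.0, 8.0):
        spec = make_model_spec("SYMIG")
        params = ScaledParams(nu_af=1, nu_bot=1, nu_eu=1, T_split=1.0,
                              T_exp=2.0, M_AtoE=m, M_EtoA=m)
        counts = simulate_sfs_counts(spec, params, 8, 8, 4_000, 3.0, 555)
        from demosfs.sfs import JointSFS

        fsts.append(hudson_fst(JointSFS(counts.astype(float))))
    assert fsts[0] > fsts[1] > fsts[2]
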