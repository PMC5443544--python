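"""Synthetic-data generator: determinism, BM identities, ground truth."""

import numpy as np
import pytest

import morphosignal as ms


class TestBMSimulation:
    def test_zero_rate_gives_zeros(self, tree14):
        tips = ms.simulate_bm_tips(tree14, 0.0, 5, seed=0)
        np.testing.assert_array_equal(tips, 0.0)

    def test_negative_rate_errors(self, tree14):
        with pytest.raises(ms.ParameterError):
            ms.simulate_bm_tips(tree14, -1.0, 2)

    def test_two_tip_variance_identity(self):
        """Var(x1 - x2) = rate * (l1 + l2) for independent root-to-tip paths."""
        tree = ms.Phylogeny.from_newick("(A:0.8,B:2.2);")
        rate = 1.7
        diffs = np.array([
            np.diff(ms.simulate_bm_tips(tree, rate, 1, seed=i)[:, 0])[0]
            for i in range(10_000)
        ])
        expected = rate * 3.0
        assert diffs.var() == pytest.approx(expected, rel=0.07)

    def test_tip_covariance_matches_tree_covariance(self):
        tree = ms.Phylogeny.from_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        rate = 0.9
        reps = np.stack([ms.simulate_bm_tips(tree, rate, 1, seed=i)[:, 0]
                         for i in range(8000)])
        emp = np.cov(reps, rowvar=False)
        np.testing.assert_allclose(emp, rate * ms.phylo_covariance(tree).C,
                                   atol=0.12)


class TestRandomTree:
    def test_structure(self):
        tree = ms.random_tree(14, np.random.default_rng(0))
        assert tree.n_tips == 14
        assert tree.is_bifurcating()
        assert tree.has_branch_lengths
        assert np.all(tree.lengths()[1:] > 0)

    def test_deterministic_given_seed(self):
        t1 = ms.random_tree(10, np.random.default_rng(5))
        t2 = ms.random_tree(10, np.random.default_rng(5))
        assert t1.to_newick() == t2.to_newick()


class TestGenerateDataset:
    def test_same_seed_identical_output(self):
        cfg = ms.SyntheticConfig(n_tips=5, n_specimens_per_species=3, seed=8)
        ds1, tr1, truth1 = ms.generate_dataset(cfg)
        ds2, tr2, truth2 = ms.generate_dataset(cfg)
        assert tr1.to_newick() == tr2.to_newick()
        assert truth1 == truth2
        for a, b in zip(ds1, ds2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_degenerate_config_collapses_pipeline(self):
        """No variation anywhere: GPA aligns all shapes identically, the tree
        length is zero, and both signal tests return p = 1."""
        cfg = ms.SyntheticConfig(n_tips=6, n_specimens_per_species=3,
                                 bm_rate=0.0, noise_sd=0.0, size_bm_rate=0.0,
                                 size_sd=0.0, seed=1)
        dataset, tree, _ = ms.generate_dataset(cfg)
        fit = ms.gpa(dataset, scale_policy="apply")
        spread = fit.tangent - fit.tangent.mean(0)
        assert np.abs(spread).max() < 1e-8
        labels, means, _ = fit.species_means()
        r = ms.tree_length_permutation_test(means, tree, n_perm=49, seed=0,
                                            tip_labels=labels)
        assert r.observed == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    def test_truth_logcs_recovered_through_scale_factor(self):
        cfg = ms.SyntheticConfig(n_tips=4, n_specimens_per_species=4, seed=9)
        dataset, _, truth = ms.generate_dataset(cfg)
        fit = ms.gpa(dataset, scale_policy="apply")
        expected = np.array([truth["specimen_logcs"][s] for s in fit.specimen_ids])
        np.testing.assert_allclose(fit.log_cs, expected, atol=1e-10)

    def test_allometry_percent_grows_with_beta(self):
        """Same seed, same noise draws: only the allometric coupling varies."""
        direction = np.zeros(16)
        direction[[1, 4, 9]] = [0.8, -0.5, 0.33]
        direction /= np.linalg.norm(direction)
        # no between-species structure (rates zero) so the percent reflects
        # the within-species allometric coupling alone
        percents = []
        for norm in (0.0, 0.1, 0.4):
            cfg = ms.SyntheticConfig(n_tips=2, n_specimens_per_species=100,
                                     bm_rate=0.0, size_bm_rate=0.0,
                                     noise_sd=1e-3,
                                     allometry_beta=norm * direction, seed=33)
            dataset, _, _ = ms.generate_dataset(cfg)
            fit = ms.gpa(dataset, scale_policy="apply")
            r = ms.regress_shape_on_size(fit.tangent, fit.log_cs, n_perm=9, seed=0)
            percents.append(r.percent_predicted)
        assert percents[0] < percents[1] < percents[2]

    def test_end_to_end_signal_recovery(self):
        """Strong Brownian structure relative to noise survives the full
        pipeline: K near 1 and a significant tree-length test."""
        cfg = ms.SyntheticConfig(n_tips=14, n_specimens_per_species=10,
                                 bm_rate=2e-3, noise_sd=2e-3, seed=77)
        dataset, tree, _ = ms.generate_dataset(cfg)
        fit = ms.gpa(dataset, scale_policy="apply")
        labels, means, _ = fit.species_means()
        tl = ms.tree_length_permutation_test(means, tree, n_perm=199, seed=0,
                                             tip_labels=labels)
        km = ms.k_mult(means, tree, n_rand=199, seed=0, tip_labels=labels)
        assert tl.p_value <= 0.05
        assert 0.5 < km.observed < 1.5


class TestNullScenario:
    def test_shuffle_preserves_configurations(self):
        cfg = ms.SyntheticConfig(n_tips=5, n_specimens_per_species=3, seed=2)
        dataset, _, _ = ms.generate_dataset(cfg)
        shuffled = ms.null_scenario(dataset, "shuffle_species", seed=0)
        orig = sorted(map(tuple, dataset.coords_array().reshape(len(dataset), -1)))
        new = sorted(map(tuple, shuffled.coords_array().reshape(len(dataset), -1)))
        assert orig == new
        assert sorted(shuffled.species_ids) == sorted(dataset.species_ids)

    def test_deterministic(self):
        cfg = ms.SyntheticConfig(n_tips=5, n_specimens_per_species=3, seed=2)
        dataset, _, _ = ms.generate_dataset(cfg)
        s1 = ms.null_scenario(dataset, "iid_species", seed=4)
        s2 = ms.null_scenario(dataset, "iid_species", seed=4)
        assert s1.species_ids == s2.species_ids

    def test_shuffled_data_reject_at_alpha(self):
        """Signal tests on species-shuffled data are correctly calibrated."""
        cfg = ms.SyntheticConfig(n_tips=10, n_specimens_per_species=5,
                                 bm_rate=2e-3, noise_sd=2e-3, seed=13)
        dataset, tree, _ = ms.generate_dataset(cfg)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            null = ms.null_scenario(dataset, "shuffle_species", seed=i)
            fit = ms.gpa(null, scale_policy="apply")
            labels, means, _ = fit.species_means()
            r = ms.tree_length_permutation_test(means, tree, n_perm=99, seed=i,
                                                tip_labels=labels)
            hits += r.p_value <= 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) <= band + 0.01
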