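"""Squared-change parsimony, tree-length permutation test, K statistic."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import optimize

import morphosignal as ms


class TestSCP:
    def test_star_tree_analytic(self):
        tree = ms.Phylogeny.from_newick("(A:1,B:1,C:1);")
        rec = ms.scp_reconstruct(np.array([[0.0], [0.0], [3.0]]), tree)
        assert rec.node_values[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert rec.tree_length == pytest.approx(6.0, abs=1e-12)

    def test_two_tip_weighted_average(self):
        tree = ms.Phylogeny.from_newick("(A:1,B:3);")
        rec = ms.scp_reconstruct(np.array([[0.0], [4.0]]), tree)
        assert rec.node_values[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert rec.tree_length == pytest.approx(4.0, abs=1e-12)

    def test_tips_equal_observations(self, tree14, rng):
        x = rng.normal(size=(14, 3))
        rec = ms.scp_reconstruct(x, tree14)
        np.testing.assert_array_equal(rec.node_values[rec.tip_indices], x)

    def test_matches_numerical_minimizer(self):
        """Internal nodes and L agree with BFGS on random <= 6-tip trees."""
        for seed in range(4):
            rng = np.random.default_rng(seed)
            tree = ms.random_tree(int(rng.integers(4, 7)), rng)
            p = 3
            x = rng.normal(size=(tree.n_tips, p))
            rec = ms.scp_reconstruct(x, tree)
            lengths = tree.lengths()
            internal = [i for i in range(tree.n_nodes) if tree.children[i]]
            tips = tree.tip_indices
            tip_rows = {t: i for i, t in enumerate(tips)}

            def objective(flat):
                vals = np.zeros((tree.n_nodes, p))
                vals[internal] = flat.reshape(len(internal), p)
                for t in tips:
                    vals[t] = x[tip_rows[t]]
                total = 0.0
                for nd in range(1, tree.n_nodes):
                    d = vals[nd] - vals[tree.parent[nd]]
                    total += float(d @ d) / lengths[nd]
                return total

            res = optimize.minimize(objective, np.zeros(len(internal) * p),
                                    method="BFGS", options={"gtol": 1e-12})
            assert rec.tree_length == pytest.approx(res.fun, abs=1e-6)
            np.testing.assert_allclose(rec.node_values[internal].ravel(),
                                       res.x, atol=1e-4)

    def test_local_optimality(self, tree14, rng):
        x = rng.normal(size=(14, 2))
        rec = ms.scp_reconstruct(x, tree14)
        lengths = tree14.lengths()

        def objective(vals):
            total = 0.0
            for nd in range(1, tree14.n_nodes):
                d = vals[nd] - vals[tree14.parent[nd]]
                total += float(d @ d) / lengths[nd]
            return total

        base = objective(rec.node_values)
        internal = [i for i in range(tree14.n_nodes) if tree14.children[i]]
        for _ in range(20):
            vals = rec.node_values.copy()
            vals[internal] += 1e-4 * rng.normal(size=(len(internal), 2))
            assert objective(vals) >= base - 1e-12

    def test_separates_by_coordinate(self, tree14, rng):
        x = rng.normal(size=(14, 4))
        joint = ms.scp_reconstruct(x, tree14)
        for j in range(4):
            single = ms.scp_reconstruct(x[:, j: j + 1], tree14)
            np.testing.assert_allclose(single.node_values[:, 0],
                                       joint.node_values[:, j], atol=1e-10)
        assert joint.tree_length == pytest.approx(
            sum(ms.scp_reconstruct(x[:, j: j + 1], tree14).tree_length
                for j in range(4)), rel=1e-10)

    def test_rotation_invariance_of_tree_length(self, tree14, rng):
        x = rng.normal(size=(14, 5))
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        l1 = ms.tree_length(x, tree14)
        l2 = ms.tree_length(x @ q, tree14)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_schur_form_matches_node_solve(self, tree14, rng):
        x = rng.normal(size=(14, 6))
        q = ms.tip_quadratic_form(tree14)
        assert float(np.sum(x * (q @ x))) == pytest.approx(
            ms.tree_length(x, tree14), rel=1e-10)


class TestTreeLengthPermutation:
    def test_identical_tip_values_give_p_one(self, tree14):
        x = np.ones((14, 3))
        r = ms.tree_length_permutation_test(x, tree14, n_perm=99, seed=0)
        assert r.p_value == 1.0
        assert r.observed == pytest.approx(0.0, abs=1e-12)

    def test_strong_bm_signal_detected(self, tree14):
        rejections = 0
        for i in range(40):
            x = ms.simulate_bm_tips(tree14, 1.0, 12, seed=300 + i)
            r = ms.tree_length_permutation_test(x, tree14, n_perm=199, seed=i)
            rejections += r.p_value <= 0.05
        assert rejections >= 38  # >= 95% power

    def test_invalid_parameters(self, tree14, balanced_tree):
        with pytest.raises(ms.ParameterError):
            ms.tree_length_permutation_test(np.zeros((14, 2)), tree14, n_perm=0)


class TestPhyloCovariance:
    def test_star_tree_identity(self):
        tree = ms.Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        np.testing.assert_allclose(ms.phylo_covariance(tree).C, np.eye(4))

    def test_path_sums(self):
        tree = ms.Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        pc = ms.phylo_covariance(tree)
        i = {l: k for k, l in enumerate(pc.tip_order)}
        assert pc.C[i["A"], i["A"]] == pytest.approx(2.0)
        assert pc.C[i["A"], i["B"]] == pytest.approx(1.0)
        assert pc.C[i["A"], i["C"]] == pytest.approx(0.0)

    def test_positive_semidefinite_random_trees(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tree = ms.random_tree(int(rng.integers(3, 12)), rng)
            eigs = np.linalg.eigvalsh(ms.phylo_covariance(tree).C)
            assert eigs.min() > -1e-10


class TestKmult:
    def test_star_tree_exactly_one(self, rng):
        tree = ms.Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        y = rng.normal(size=(5, 7))
        k = ms.k_mult_statistic(y, ms.phylo_covariance(tree).C)
        assert k == pytest.approx(1.0, abs=1e-12)

    def test_univariate_matches_picante_kcalc(self, tmp_path):
        """p = 1 reduces to Blomberg's K; cross-checked against the R
        implementation in picante."""
        newick = "((A:1.2,B:0.7):0.5,(C:0.3,D:1.1):0.9,E:2.0);"
        tree = ms.Phylogeny.from_newick(newick)
        values = {"A": 0.3, "B": -1.2, "C": 2.1, "D": 0.4, "E": -0.7}
        y = np.array([[values[l]] for l in tree.tip_labels])
        ours = ms.k_mult_statistic(y, ms.phylo_covariance(tree).C)

        script = tmp_path / "kcalc.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages({{library(ape); library(picante)}})
            tree <- read.tree(text="{newick}")
            x <- c(A=0.3, B=-1.2, C=2.1, D=0.4, E=-0.7)
            cat(sprintf("%.12f", Kcalc(x[tree$tip.label], tree)))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        assert ours == pytest.approx(float(out.stdout.strip()), abs=1e-8)

    def test_univariate_matches_gls_route(self, balanced_tree, rng):
        """Second independent route: whitened GLS sums of squares."""
        y = rng.normal(size=(4, 1))
        c = ms.phylo_covariance(balanced_tree).C
        n = 4
        chol = np.linalg.cholesky(c)
        z = np.linalg.solve(chol, y)
        one_w = np.linalg.solve(chol, np.ones((n, 1)))
        a = np.linalg.lstsq(one_w, z, rcond=None)[0].item()
        e = y - a
        num = (e.T @ e).item() / ((z - one_w * a).T @ (z - one_w * a)).item()
        den = (np.trace(c) - n / (one_w.T @ one_w).item()) / (n - 1)
        expected = num / den
        assert ms.k_mult_statistic(y, c) == pytest.approx(expected, abs=1e-8)

    def test_branch_length_scaling_invariance(self, tree14, rng):
        y = rng.normal(size=(14, 5))
        c = ms.phylo_covariance(tree14).C
        k1 = ms.k_mult_statistic(y, c)
        k2 = ms.k_mult_statistic(y, 7.3 * c)
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_bm_monte_carlo_mean_near_one(self, tree14):
        ks = [ms.k_mult_statistic(ms.simulate_bm_tips(tree14, 1.0, 12, seed=i),
                                  ms.phylo_covariance(tree14).C)
              for i in range(500)]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_randomization_null_below_bm_observed(self, tree14):
        y = ms.simulate_bm_tips(tree14, 1.0, 12, seed=99)
        r = ms.k_mult(y, tree14, n_rand=199, seed=1)
        assert r.statistic_name == "k_mult"
        assert np.mean(r.null_draws) < r.observed
        assert r.p_value <= 0.05


class TestPhylomorphospace:
    def test_linearity_with_loadings(self, tree14, rng):
        """Reconstructing scores equals projecting full-space reconstructions."""
        full = rng.normal(size=(14, 10))
        res = ms.shape_pca(full)
        scores = res.scores[:, :2]
        nodes_scores, edges, _ = ms.phylomorphospace(scores, tree14)
        rec_full = ms.scp_reconstruct(full - res.mean_vector, tree14)
        projected = rec_full.node_values @ res.loadings[:2].T
        np.testing.assert_allclose(nodes_scores, projected, atol=1e-8)
        assert len(edges) == tree14.n_nodes - 1

    def test_star_tree_root_at_weighted_centroid(self, rng):
        tree = ms.Phylogeny.from_newick("(A:1,B:2,C:4,D:4);")
        scores = rng.normal(size=(4, 2))
        nodes, _, _ = ms.phylomorphospace(scores, tree)
        w = 1.0 / np.array([1.0, 2.0, 4.0, 4.0])
        expected = (w[:, None] * scores).sum(0) / w.sum()
        np.testing.assert_allclose(nodes[0], expected, atol=1e-10)
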