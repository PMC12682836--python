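"""Tree covariance, Blomberg's K, ancestral states, PGLS, tip-rate tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mnminer import (
    TraitVector,
    asr_ml,
    blomberg_k,
    pgls,
    phylo_vcv,
    read_newick,
    tip_rate_tests,
)
from mnminer.phylo import ConstantTraitError, TipRateVector
from mnminer.simulate import gen_tree_traits_rates


def bruteforce_vcv(phy):
    """Independent oracle: shared path length via root-path edge sets."""
    tree = phy.tree
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        if tree.seed_node.edge.length:
            edges.append((id(tree.seed_node), tree.seed_node.edge.length))
        paths[leaf.taxon.label] = dict(edges)
    labels = sorted(paths)
    n = len(labels)
    v = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b]) if i != j else set(paths[a])
            v[i, j] = sum(paths[a][e] for e in shared)
    return pd.DataFrame(v, index=labels, columns=labels)


class TestVcv:
    def test_star_tree_is_identity(self):
        phy = read_newick("(A:1,B:1,C:1,D:1);")
        np.testing.assert_allclose(phylo_vcv(phy).to_numpy(), np.eye(4))

    def test_three_tip_example(self):
        phy = read_newick("((A:1,B:1):1,C:2);")
        expected = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        np.testing.assert_allclose(phylo_vcv(phy).to_numpy(), expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_trees(self, seed):
        phy, _, _, _ = gen_tree_traits_rates(n_tips=20, seed=seed)
        ours = phylo_vcv(phy)
        oracle = bruteforce_vcv(phy)
        np.testing.assert_allclose(
            ours.to_numpy(), oracle.loc[ours.index, ours.columns].to_numpy(),
            atol=1e-12,
        )


class TestBlombergK:
    def _four_tip(self):
        phy = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        trait = TraitVector({"A": 1.0, "B": 2.0, "C": 4.0, "D": 8.0})
        return phy, trait

    def test_matches_exact_arithmetic_oracle(self):
        """Spreadsheet-style evaluation of the full formula chain with sympy."""
        import sympy as sp

        phy, trait = self._four_tip()
        v = sp.Matrix([[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]])
        y = sp.Matrix([1, 2, 4, 8])
        one = sp.ones(4, 1)
        vinv = v.inv()
        ahat = (one.T * vinv * y)[0] / (one.T * vinv * one)[0]
        r = y - ahat * one
        mse0 = (r.T * r)[0] / 3
        mse = (r.T * vinv * r)[0] / 3
        expected_ratio = (v.trace() - 4 / (one.T * vinv * one)[0]) / 3
        k_exact = float((mse0 / mse) / expected_ratio)
        res = blomberg_k(phy, trait, n_perm=0)
        assert res.k == pytest.approx(k_exact, abs=1e-10)

    def test_matches_independent_implementation(self):
        """Frozen reference value from an independent R implementation
        (phytools::phylosig) on a fixed 10-tip tree and trait."""
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=10, seed=42)
        res = blomberg_k(phy, trait, n_perm=0)
        assert res.k == pytest.approx(1.10062913479625, abs=1e-9)

    def test_affine_invariance(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=15, seed=3)
        k0 = blomberg_k(phy, trait, n_perm=0).k
        shifted = TraitVector({t: -2.5 * v + 7.0 for t, v in trait.values.items()})
        assert blomberg_k(phy, shifted, n_perm=0).k == pytest.approx(k0, abs=1e-9)

    def test_mean_k_near_one_under_brownian_motion(self):
        ks = []
        for seed in range(100):
            phy, trait, _, _ = gen_tree_traits_rates(n_tips=50, seed=seed)
            ks.append(blomberg_k(phy, trait, n_perm=0).k)
        assert 0.85 <= np.mean(ks) <= 1.15

    def test_shuffled_traits_lose_signal(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=50, seed=1)
        rng = np.random.default_rng(0)
        ks = []
        for _ in range(50):
            vals = rng.permutation(list(trait.values.values()))
            shuffled = TraitVector(dict(zip(trait.values, vals)))
            ks.append(blomberg_k(phy, shuffled, n_perm=0).k)
        assert np.median(ks) < 1.0

    def test_permutation_p_reproducible_given_seed(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=20, seed=2)
        a = blomberg_k(phy, trait, n_perm=500, seed=9)
        b = blomberg_k(phy, trait, n_perm=500, seed=9)
        assert a.p == b.p
        assert 1 / 501 <= a.p <= 1.0

    def test_constant_trait_rejected(self):
        phy, _, _, _ = gen_tree_traits_rates(n_tips=10, seed=0)
        const = TraitVector({t: 1.0 for t in phy.tip_labels})
        with pytest.raises(ConstantTraitError):
            blomberg_k(phy, const)

    def test_missing_tip_value_rejected(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=10, seed=0)
        partial = dict(trait.values)
        partial.pop(next(iter(partial)))
        with pytest.raises(KeyError, match="missing"):
            blomberg_k(phy, TraitVector(partial))


class TestAsr:
    def test_constant_trait_everywhere_constant(self):
        phy = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = asr_ml(phy, TraitVector({t: 3.5 for t in "ABCD"}))
        np.testing.assert_allclose(res["nodes"].state.to_numpy(), 3.5)

    def test_two_tip_closed_form(self):
        phy = read_newick("(A:1,B:3);")
        res = asr_ml(phy, TraitVector({"A": 0.0, "B": 4.0}))
        # inverse-branch-length weighted mean
        expected = (0.0 / 1 + 4.0 / 3) / (1 / 1 + 1 / 3)
        assert res["root"] == pytest.approx(expected, abs=1e-10)

    def test_root_equals_phylogenetic_mean(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=12, seed=5)
        res = asr_ml(phy, trait)
        assert res["root"] == pytest.approx(res["phylo_mean"], abs=1e-10)

    def test_matches_mvn_conditional_oracle(self):
        """Joint tips+nodes covariance built independently, then standard
        multivariate-normal conditioning."""
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=6, seed=8)
        tree = phy.tree
        for node in tree.preorder_node_iter():
            pd_ = 0.0 if node.parent_node is None else node.parent_node._od
            node._od = pd_ + (node.edge.length or 0.0)
        nodes = list(tree.preorder_node_iter())

        def mrca_depth(a, b):
            anc_a = set()
            x = a
            while x is not None:
                anc_a.add(id(x))
                x = x.parent_node
            x = b
            while x is not None:
                if id(x) in anc_a:
                    return x._od
                x = x.parent_node
            return 0.0

        tips = sorted([n for n in nodes if n.is_leaf()],
                      key=lambda n: n.taxon.label)
        internal = [n for n in nodes if not n.is_leaf()]
        y = np.array([trait.values[t.taxon.label] for t in tips])
        v_tt = np.array([[mrca_depth(a, b) if a is not b else a._od
                          for b in tips] for a in tips])
        c_nt = np.array([[mrca_depth(nd, t) for t in tips] for nd in internal])
        vinv = np.linalg.inv(v_tt)
        one = np.ones(len(tips))
        ahat = (one @ vinv @ y) / (one @ vinv @ one)
        oracle = ahat + c_nt @ vinv @ (y - ahat)

        res = asr_ml(phy, trait)
        states = res["nodes"].sort_index().state.to_numpy()
        # implementation enumerates internal nodes in the same preorder
        np.testing.assert_allclose(states, oracle, atol=1e-8)

    def test_branch_interpolation_is_linear(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=6, seed=8)
        res = asr_ml(phy, trait)
        f = res["interpolate"]
        assert f(1.0, 3.0, 0.5) == pytest.approx(2.0)
        assert f(1.0, 3.0, 0.0) == 1.0 and f(1.0, 3.0, 1.0) == 3.0


class TestPgls:
    def test_star_tree_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)]
        star = read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        x = rng.normal(size=8)
        y = 2 * x + rng.normal(size=8)
        fit = pgls(star, TraitVector(dict(zip(labels, y))),
                   TraitVector(dict(zip(labels, x)), name="x"))
        ols = sm.OLS(y[np.argsort(labels)], sm.add_constant(x[np.argsort(labels)])).fit()
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.pvalues["slope"] == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_exact_linear_relationship(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=10, seed=4)
        y = TraitVector({t: 3.0 * v + 1.0 for t, v in trait.values.items()})
        fit = pgls(phy, y, trait)
        assert fit.slope == pytest.approx(3.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_three_tip_hand_matrix_oracle(self):
        phy = read_newick("((A:1,B:1):1,C:2);")
        x = {"A": 0.0, "B": 1.0, "C": 2.0}
        y = {"A": 0.2, "B": 1.1, "C": 1.9}
        v = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        design = np.column_stack([np.ones(3), [x["A"], x["B"], x["C"]]])
        yv = np.array([y["A"], y["B"], y["C"]])
        vinv = np.linalg.inv(v)
        a = design.T @ vinv @ design
        # explicit 2x2 inversion
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        ainv = np.array([[a[1, 1], -a[0, 1]], [-a[1, 0], a[0, 0]]]) / det
        beta = ainv @ design.T @ vinv @ yv
        fit = pgls(phy, TraitVector(y), TraitVector(x, name="x"))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_collinear_design_rejected(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=6, seed=1)
        const = TraitVector({t: 2.0 for t in trait.values})
        with pytest.raises(ValueError, match="collinear"):
            pgls(phy, trait, const)


class TestTipRates:
    def test_monotone_rates_give_extreme_rho(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=10, seed=6)
        order = sorted(trait.values, key=trait.values.get)
        up = TipRateVector({t: float(i + 1) for i, t in enumerate(order)})
        down = TipRateVector({t: float(len(order) - i) for i, t in enumerate(order)})
        res_up = tip_rate_tests(up, [trait], phy)
        res_down = tip_rate_tests(down, [trait], phy)
        assert res_up.spearman_rho[0] == pytest.approx(1.0)
        assert res_down.spearman_rho[0] == pytest.approx(-1.0)

    def test_exact_p_matches_full_enumeration_with_tie(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=6, seed=9)
        tips = sorted(trait.values)
        rates = TipRateVector(dict(zip(tips, [1.0, 2.0, 2.0, 3.0, 5.0, 4.0])))
        res = tip_rate_tests(rates, [trait], phy)
        assert res.spearman_p_kind[0] == "exact"
        x = np.array([trait.values[t] for t in tips])
        r = np.array([rates.values[t] for t in tips])
        rho_obs = stats.spearmanr(r, x).statistic
        assert res.spearman_rho[0] == pytest.approx(rho_obs)
        # oracle: enumerate all 720 pairings of raw values
        count = sum(
            abs(stats.spearmanr(np.array(perm), x).statistic) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(r)
        )
        assert res.spearman_p[0] == pytest.approx(count / math.factorial(6))

    def test_all_tied_rates_rejected(self):
        phy, trait, _, _ = gen_tree_traits_rates(n_tips=6, seed=2)
        tied = TipRateVector({t: 1.0 for t in trait.values})
        with pytest.raises(ValueError, match="tied"):
            tip_rate_tests(tied, [trait], phy)

    def test_recovers_negative_rate_trait_link(self):
        neg = 0
        for seed in range(30):
            phy, trait, rates, _ = gen_tree_traits_rates(
                n_tips=50, rate_slope=-1.0, rate_noise_sd=0.1, seed=seed,
            )
            res = tip_rate_tests(rates, [trait], phy)
            neg += res.spearman_rho[0] < 0
        assert neg >= 29
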