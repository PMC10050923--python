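"""Comparative statistics: trees, BM simulation, rank tests, PGLS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from billmech import phylo


def tree_from(newick: str) -> phylo.Phylogeny:
    return phylo._phylogeny_from_newick_string(newick)


class TestPhylogeny:
    def test_covariance_from_shared_paths(self):
        t = tree_from("((A:1,B:1):1,C:2);")
        C = t.cov_matrix()
        i = {l: k for k, l in enumerate(t.tip_labels)}
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["A"]] == pytest.approx(2.0)
        assert C[i["A"], i["C"]] == 0.0

    def test_star_tree_is_diagonal(self):
        C = tree_from("(A:1,B:1,C:1);").cov_matrix()
        assert np.allclose(C, np.eye(3))

    def test_duplicate_tip_labels_rejected(self, tmp_path):
        (tmp_path / "dup.nwk").write_text("(A:1,(A:0.5,B:0.5):0.5);\n")
        with pytest.raises(ValueError, match="[Mm]ultiple|duplicate"):
            phylo.read_newick(tmp_path / "dup.nwk")

    def test_malformed_newick_rejected(self, tmp_path):
        (tmp_path / "bad.nwk").write_text("((A:1,B:1):1\n")
        with pytest.raises(ValueError, match="malformed"):
            phylo.read_newick(tmp_path / "bad.nwk")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch lengths"):
            tree_from("((A:1,B),C:2);").cov_matrix()

    def test_newick_round_trip(self, tmp_path):
        t = phylo.simulate_yule(10, seed=3)
        phylo.write_newick(t, tmp_path / "t.nwk")
        back = phylo.read_newick(tmp_path / "t.nwk")
        assert sorted(back.tip_labels) == sorted(t.tip_labels)
        order = [back.tip_labels.index(l) for l in t.tip_labels]
        assert np.allclose(back.cov_matrix()[np.ix_(order, order)], t.cov_matrix())


class TestTreeSimulation:
    def test_yule_is_ultrametric_with_unit_height(self):
        t = phylo.simulate_yule(20, seed=1)
        C = t.cov_matrix()
        assert np.allclose(np.diag(C), 1.0)

    def test_split_clade_sizes_and_height(self):
        rng = np.random.default_rng(5)
        t = phylo.simulate_split_clade((7, 8), rng=rng)
        assert t.n_tips == 15
        assert np.allclose(np.diag(t.cov_matrix()), 1.0)


class TestBMSimulation:
    def test_zero_rate_returns_root_value(self):
        t = phylo.simulate_yule(6, seed=2)
        out = phylo.bm_simulate(t, 1e-30, seed=0, root_value=3.5)
        assert np.allclose(out["trait_0"], 3.5, atol=1e-10)

    def test_seed_determinism(self):
        t = phylo.simulate_yule(8, seed=2)
        a = phylo.bm_simulate(t, 1.0, seed=9)
        b = phylo.bm_simulate(t, 1.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_tip_covariance_matches_closed_form(self):
        """Empirical covariance over replicates approaches sigma^2 C."""
        t = tree_from("((A:1,B:1):1,C:2);")
        rng = np.random.default_rng(0)
        sims = np.array([phylo.bm_simulate(t, 2.0, rng=rng).to_numpy().ravel()
                         for _ in range(500)])
        emp = np.cov(sims.T)
        expected = 2.0 * t.cov_matrix()
        assert np.abs(emp - expected).max() <= 0.15 * expected.max()

    def test_rate_matrix_must_be_positive_definite(self):
        t = phylo.simulate_yule(5, seed=0)
        with pytest.raises(ValueError, match="positive definite"):
            phylo.bm_simulate(t, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0)


class TestSpearman:
    def test_perfect_monotone(self):
        assert phylo.spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert phylo.spearman([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = phylo.spearman(x, y)
        trans = phylo.spearman(np.exp(x), y**3)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)
        assert trans.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=7), rng.normal(size=7)
        res = phylo.spearman(x, y)
        assert res.method == "exact-permutation"
        rx = st.rankdata(x)
        count = sum(
            abs(st.spearmanr(rx, perm).statistic) >= abs(res.rho) - 1e-9
            for perm in itertools.permutations(st.rankdata(y))
        )
        assert res.p_value == pytest.approx(count / math.factorial(7), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = phylo.spearman(x, y)
        assert res.method == "t-approximation"
        assert res.p_value == pytest.approx(st.spearmanr(x, y).pvalue, rel=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            phylo.spearman([1, 2], [3, 4])


class TestWilcoxon:
    def test_exact_p_matches_sign_enumeration(self):
        d = np.array([1.2, -0.4, 2.2, 0.9, -1.1, 0.3, 1.7, 0.8])
        p = phylo.wilcoxon_signed_rank(d, np.zeros(len(d)))
        ranks = st.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ])
        expected = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_three_positive_differences(self):
        # W+ = 6 over 8 equally likely sign assignments: two-sided p = 0.25
        assert phylo.wilcoxon_signed_rank([1.0, 2.0, 3.0]) == pytest.approx(0.25)

    def test_antisymmetric_differences_same_p(self):
        d = np.array([0.7, -1.9, 2.3, 0.5, -0.2, 1.4])
        assert phylo.wilcoxon_signed_rank(d) == pytest.approx(
            phylo.wilcoxon_signed_rank(-d[::-1]), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            phylo.wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=25)
        exact = phylo.wilcoxon_signed_rank(d)
        approx = phylo.wilcoxon_signed_rank(d, exact_max_n=10)
        assert approx == pytest.approx(exact, rel=0.1)


class TestPGLS:
    def test_fixed0_equals_ols(self):
        tree = phylo.simulate_yule(20, seed=5)
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        fit = phylo.pgls(y, x, tree, "fixed0")
        ols = st.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-10)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-10)
        assert fit.p_value == pytest.approx(ols.pvalue, rel=1e-9)

    def test_star_tree_ml_fit_equals_ols(self):
        star = tree_from("(" + ",".join(f"t{i}:1" for i in range(10)) + ");")
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = 1.5 * x + rng.normal(size=10)
        fit = phylo.pgls(y, x, star, "ml")
        ols = st.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-10)

    def test_fixed1_equals_independent_contrasts_slope(self):
        """PGLS under Brownian motion equals the contrasts regression through
        the origin - the classical equivalence, with contrasts computed here
        by Felsenstein pruning as the oracle."""
        tree = phylo.simulate_yule(24, seed=11)
        x = phylo.bm_simulate(tree, 1.0, seed=21)["trait_0"].to_numpy()
        y = 2 * x + phylo.bm_simulate(tree, 0.5, seed=22)["trait_0"].to_numpy()
        fit = phylo.pgls(y, x, tree, "fixed1")
        assert fit.slope == pytest.approx(_pic_slope(tree, x, y), abs=1e-8)

    def test_ml_lambda_near_grid_argmax(self):
        tree = phylo.simulate_yule(32, seed=3)
        x = phylo.bm_simulate(tree, 1.0, seed=31)["trait_0"].to_numpy()
        y = x + phylo.bm_simulate(tree, 1.0, seed=32)["trait_0"].to_numpy()
        fit = phylo.pgls(y, x, tree, "ml")
        grid = np.linspace(0, 1, 1001)
        X = np.column_stack([np.ones(32), x])
        lls = [phylo._profile_ll(y, X, tree.cov_matrix(), g) for g in grid]
        assert abs(fit.lambda_ - grid[int(np.argmax(lls))]) <= 1e-3 + 1e-9

    def test_boundary_lambda_bound_test_returns_one(self):
        star = tree_from("(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(size=12)
        fit = phylo.pgls(y, x, star, "ml")
        assert fit.lambda_ == 0.0
        assert fit.lambda_bounds["lambda0"] == 1.0
        assert 0 < fit.lambda_bounds["lambda1"] <= 1.0

    def test_too_few_tips_rejected(self):
        t = tree_from("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            phylo.pgls([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], t, "fixed0")


def _pic_slope(tree: phylo.Phylogeny, xv: np.ndarray, yv: np.ndarray) -> float:
    """Independent-contrasts slope through the origin (Felsenstein pruning)."""
    t = tree.tree.clone(depth=1)
    vals = {}
    for leaf in t.leaf_node_iter():
        i = tree.tip_labels.index(leaf.taxon.label)
        vals[id(leaf)] = (xv[i], yv[i], leaf.edge.length)
    cx, cy = [], []
    for node in t.postorder_node_iter():
        if node.is_leaf():
            continue
        (x1, y1, v1), (x2, y2, v2) = (vals[id(c)] for c in node.child_nodes())
        cx.append((x1 - x2) / math.sqrt(v1 + v2))
        cy.append((y1 - y2) / math.sqrt(v1 + v2))
        xa = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        ya = (y1 / v1 + y2 / v2) / (1 / v1 + 1 / v2)
        vals[id(node)] = (xa, ya, (node.edge.length or 0.0) + v1 * v2 / (v1 + v2))
    cx, cy = np.array(cx), np.array(cy)
    return float(cx @ cy / (cx @ cx))


class TestPhylPairedT:
    def test_star_tree_equals_ordinary_paired_t(self):
        star = tree_from("(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
        rng = np.random.default_rng(7)
        y1 = rng.normal(size=12)
        y2 = y1 - (0.4 + rng.normal(size=12))
        res = phylo.phyl_paired_ttest(y1, y2, star)
        assert res.p_value == pytest.approx(st.ttest_rel(y1, y2).pvalue, abs=1e-6)
        assert res.df == pytest.approx(11.0)

    def test_constant_shift_rejected(self):
        t = phylo.simulate_yule(8, seed=0)
        y1 = phylo.bm_simulate(t, 1.0, seed=5)["trait_0"].to_numpy()
        with pytest.raises(ValueError, match="zero variance"):
            phylo.phyl_paired_ttest(y1, y1 + 0.7, t)

    def test_detects_a_real_shift(self):
        t = phylo.simulate_yule(15, seed=4)
        rng = np.random.default_rng(0)
        y1 = phylo.bm_simulate(t, 0.05, rng=rng)["trait_0"].to_numpy()
        y2 = y1 + 3.0 + phylo.bm_simulate(t, 0.05, rng=rng)["trait_0"].to_numpy()
        assert phylo.phyl_paired_ttest(y2, y1, t).p_value < 0.001


@pytest.fixture(scope="module")
def table_and_tree():
    rng = np.random.default_rng(6)
    tree = phylo.simulate_split_clade((4, 4), rng=rng)
    size = np.linspace(1.0, 2.0, 8)  # monotone size axis across species
    table = pd.DataFrame(
        {
            "peak_vm_impact": 1e5 / size,
            "peak_vm_torsion": 4e5 * size,
            "sigma_cr": 1e8 * size**2,
            "tau_max": 6e5 * size,
            "width": 0.01 * size,
            "depth": 0.012 * size,
            "body_length": 20 + size,
        },
        index=tree.tip_labels,
    )
    return table, tree


class TestCorrelationSuite:

    def test_constructed_antimonotone_pair_gives_rho_minus_one(self, table_and_tree):
        table, tree = table_and_tree
        report = phylo.run_correlation_suite(table, tree)
        row = report[(report.predictor == "peak_vm_torsion")
                     & (report.lambda_mode == "ml")].iloc[0]
        assert row.spearman_rho == pytest.approx(-1.0)

    def test_report_has_five_models_by_three_treatments(self, table_and_tree):
        table, tree = table_and_tree
        report = phylo.run_correlation_suite(table, tree)
        assert len(report) == 15
        assert set(report.lambda_mode) == {"ml", "fixed0", "fixed1"}
        assert report.groupby(["predictor", "response"]).size().eq(3).all()

    def test_misaligned_labels_rejected(self, table_and_tree):
        table, tree = table_and_tree
        shuffled = table.copy()
        shuffled.index = [f"other{i}" for i in range(len(table))]
        with pytest.raises(ValueError, match="labels"):
            phylo.run_correlation_suite(shuffled, tree)

    def test_nonpositive_performance_rejected(self, table_and_tree):
        table, tree = table_and_tree
        bad = table.copy()
        bad.loc[bad.index[0], "sigma_cr"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            phylo.run_correlation_suite(bad, tree)
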