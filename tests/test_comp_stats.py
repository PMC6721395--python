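"""Phylogenetic ANOVA, Holm correction, PGLS, and the sister-pair scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from songevo.comp_stats import (
    anova_f,
    fit_pgls,
    holm,
    phyl_anova,
    sister_pair_rate_scan,
)
from songevo.mk_ctmc import er_generator
from songevo.phylo_core import linearize, parse_newick, phylo_covariance
from songevo.synthetic_data import simulate_bm_regimes, simulate_discrete, simulate_yule


class TestAnovaF:
    def test_hand_computed_example(self):
        assert anova_f(np.array([0.0, 1.0, 2.0, 3.0]), ["a", "a", "b", "b"]) == 8.0

    def test_identical_group_means_give_zero(self):
        assert anova_f(np.array([0.0, 2.0, 0.0, 2.0]), ["a", "a", "b", "b"]) == 0.0

    def test_matches_scipy_oracle(self, rng):
        x = rng.normal(size=30)
        g = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 8)
        expected = stats.f_oneway(x[g == "a"], x[g == "b"], x[g == "c"]).statistic
        assert anova_f(x, g) == pytest.approx(expected, abs=1e-10)

    def test_zero_within_variance_is_infinite(self):
        assert anova_f(np.array([1.0, 1.0, 2.0, 2.0]), ["a", "a", "b", "b"]) == np.inf


class TestPhylAnova:
    def _data(self, seed=0, shift=0.0, n=50):
        tree = simulate_yule(n, seed=seed)
        tips, smap = simulate_discrete(tree, er_generator(2, 0.7), ("s", "p"), "s", seed=seed)
        vals = simulate_bm_regimes(
            tree, smap, {"s": 1.0, "p": 1.0},
            state_offsets={"s": 0.0, "p": shift}, seed=seed + 1,
        )
        return tree, vals, tips

    def test_fixed_seed_reproducible(self):
        tree, vals, tips = self._data()
        r1 = phyl_anova(tree, vals, tips, n_sim=200, seed=3)
        r2 = phyl_anova(tree, vals, tips, n_sim=200, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.posthoc_p == r2.posthoc_p

    def test_observed_f_is_tree_free(self):
        tree, vals, tips = self._data(seed=1)
        res = phyl_anova(tree, vals, tips, n_sim=200, seed=0, posthoc=False)
        labels = [l for l in vals if tips.get(l) is not None]
        f_direct = anova_f(
            np.array([vals[l] for l in labels]),
            np.array([tips[l] for l in labels], dtype=object),
        )
        # same data on a rewired tree: F unchanged, only p may move
        other = simulate_yule(50, seed=99)
        relab = dict(zip(other.tip_labels, labels))
        other_vals = {t: vals[relab[t]] for t in other.tip_labels}
        other_groups = {t: tips[relab[t]] for t in other.tip_labels}
        res2 = phyl_anova(other, other_vals, other_groups, n_sim=200, seed=0, posthoc=False)
        assert res.f_observed == pytest.approx(f_direct, abs=1e-10)
        assert res2.f_observed == pytest.approx(f_direct, abs=1e-10)

    def test_strong_shift_detected(self):
        tree, vals, tips = self._data(seed=2, shift=5.0)
        res = phyl_anova(tree, vals, tips, n_sim=500, seed=0)
        assert res.p_value <= 0.01
        assert res.posthoc_p[tuple(sorted(("s", "p")))] <= 0.05

    def test_pvalue_never_zero(self):
        tree, vals, tips = self._data(seed=3, shift=20.0)
        res = phyl_anova(tree, vals, tips, n_sim=200, seed=0, posthoc=False)
        assert res.p_value >= 1.0 / 201


class TestHolm:
    def test_seven_test_ladder(self):
        res = holm([0.001] * 7)
        assert np.allclose(
            np.sort(res.thresholds),
            [1 / 140, 1 / 120, 0.01, 0.0125, 1 / 60, 0.025, 0.05],
            atol=5e-5,
        )

    def test_single_test(self):
        assert holm([0.2]).thresholds[0] == 0.05

    def test_all_ones_reject_nothing(self):
        assert not holm([1.0, 1.0, 1.0]).reject.any()

    def test_sequential_stop_at_first_failure(self):
        res = holm([0.001, 0.04, 0.012])
        # sorted: 0.001<=0.05/3 ok; 0.012<=0.025 ok; 0.04<=0.05 ok
        assert res.reject.all()
        res2 = holm([0.001, 0.04, 0.03])
        # sorted: 0.001 ok; 0.03>0.025 stop; 0.04 not tested
        assert list(res2.reject) == [True, False, False]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_between_bonferroni_and_unadjusted(self, ps):
        m = len(ps)
        res = holm(ps)
        bonf = np.asarray(ps) <= 0.05 / m
        raw = np.asarray(ps) <= 0.05
        assert (res.reject | ~bonf).all()  # Holm rejects superset of Bonferroni
        assert (~res.reject | raw).all()  # and subset of unadjusted


class TestPgls:
    def _xy(self, seed=0, n=60, slope=0.9):
        tree = simulate_yule(n, seed=seed)
        tips, smap = simulate_discrete(tree, er_generator(2, 0.7), ("s", "p"), "s", seed=seed)
        x = simulate_bm_regimes(tree, smap, {"s": 1.0, "p": 1.0}, seed=seed + 1)
        resid = simulate_bm_regimes(tree, smap, {"s": 0.3, "p": 0.3}, seed=seed + 2)
        y = {l: slope * x[l] + resid[l] for l in x}
        return tree, y, x

    def test_lambda_zero_reduces_to_ols(self):
        tree, y, x = self._xy()
        fit = fit_pgls(tree, y, x, lam=0.0)
        labels = linearize(tree).tip_labels
        ols = stats.linregress([x[l] for l in labels], [y[l] for l in labels])
        assert fit.slope == pytest.approx(ols.slope, abs=1e-10)
        assert fit.std_error == pytest.approx(ols.stderr, abs=1e-10)
        assert fit.p_value == pytest.approx(ols.pvalue, abs=1e-10)

    def test_lambda_one_reduces_to_plain_gls(self):
        tree, y, x = self._xy(seed=1)
        fit = fit_pgls(tree, y, x, lam=1.0)
        labels = linearize(tree).tip_labels
        C, _ = phylo_covariance(tree, order=labels)
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        X = np.column_stack([np.ones(len(labels)), [x[l] for l in labels]])
        yv = np.array([y[l] for l in labels])
        Ri = np.linalg.inv(R)
        beta = np.linalg.solve(X.T @ Ri @ X, X.T @ Ri @ yv)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_profile_lambda_recovers_generative_slope(self):
        slopes = []
        for seed in range(8):
            tree, y, x = self._xy(seed=10 + seed, n=120)
            fit = fit_pgls(tree, y, x)
            assert 0.0 <= fit.lam <= fit.lam_max
            slopes.append(fit.slope)
        assert abs(np.mean(slopes) - 0.9) < 0.15

    def test_too_few_rows_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            fit_pgls(three_tip_tree, {"A": 1.0, "B": 2.0}, {"A": 0.0, "B": 1.0})


class TestSisterPairs:
    def test_identical_pair_values_flagged_degenerate(self):
        tree = parse_newick("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):2):1);")
        vals = {l: 1.0 for l in tree.tip_labels}
        res = sister_pair_rate_scan(tree, vals)
        assert res["degenerate"]

    def test_null_bm_correlation_near_zero(self):
        hits = 0
        for seed in range(10):
            tree = simulate_yule(60, seed=40 + seed)
            tips, smap = simulate_discrete(tree, er_generator(2, 0.5), ("s", "p"), "s", seed=seed)
            vals = simulate_bm_regimes(tree, smap, {"s": 1.0, "p": 1.0}, seed=seed)
            res = sister_pair_rate_scan(tree, vals, n_perm=200, seed=seed)
            hits += abs(res["rho"]) < 0.5
        assert hits >= 8

    def test_planted_rate_size_association_detected(self):
        detected = 0
        for seed in range(6):
            tree = simulate_yule(80, seed=70 + seed)
            tips, smap = simulate_discrete(tree, er_generator(2, 0.5), ("s", "p"), "s", seed=seed)
            vals = simulate_bm_regimes(tree, smap, {"s": 1.0, "p": 1.0}, seed=seed)
            # inflate contrasts of high-mean cherries
            for node in tree.postorder():
                kids = tree.children[node]
                if len(kids) == 2 and all(tree.is_tip(c) for c in kids):
                    l1, l2 = tree.labels[kids[0]], tree.labels[kids[1]]
                    if 0.5 * (vals[l1] + vals[l2]) > np.median(list(vals.values())):
                        vals[l1] = vals[l1] + 3.0 * (vals[l1] - vals[l2])
            res = sister_pair_rate_scan(tree, vals, n_perm=300, seed=seed)
            detected += res["p_value"] < 0.05 and res["rho"] > 0
        assert detected >= 4

    def test_too_few_cherries_raises(self, three_tip_tree):
        with pytest.raises(ValueError):
            sister_pair_rate_scan(three_tip_tree, {"A": 1.0, "B": 2.0, "C": 3.0})
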