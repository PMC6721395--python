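"""Correlated-evolution models, threshold sweep, and binned summaries."""

import itertools
import math

import numpy as np
import pytest

from songevo.mk_ctmc import MkModel, ard_generator, mk_loglik, transition_probability
from songevo.pagel_sweep import (
    DEP_RATE_NAMES,
    PAIR_STATES,
    _bin_sizes,
    dependent_generator,
    fit_pagel_pair,
    independent_generator,
    pagel_loglik,
    run_pagel_binary,
    summarize_sweep,
    threshold_sweep,
)
from songevo.synthetic_data import simulate_dependent_pair, simulate_yule


class TestGenerators:
    def test_dual_transitions_are_structural_zeros(self):
        Q = dependent_generator(np.arange(1, 9, dtype=float))
        assert Q[0, 3] == Q[3, 0] == Q[1, 2] == Q[2, 1] == 0.0
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_independent_generator_ties_four_pairs(self):
        Q = independent_generator(0.3, 0.7, 1.1, 1.9)
        # trait1 gain rate identical whatever trait2's state
        assert Q[0, 2] == Q[1, 3] == 0.3
        assert Q[2, 0] == Q[3, 1] == 0.7
        assert Q[0, 1] == Q[2, 3] == 1.1
        assert Q[1, 0] == Q[3, 2] == 1.9


class TestLikelihood:
    def test_independent_model_equals_sum_of_marginal_chains(self, five_tip_tree):
        rng = np.random.default_rng(0)
        g1, l1, g2, l2 = rng.uniform(0.2, 2.0, 4)
        pairs = {"A": (0, 0), "B": (0, 1), "C": (1, 0), "D": (1, 1), "E": (0, 0)}
        ll4 = pagel_loglik(five_tip_tree, pairs, independent_generator(g1, l1, g2, l2))
        m1 = MkModel((0, 1), ard_generator(2, [g1, l1]))
        m2 = MkModel((0, 1), ard_generator(2, [g2, l2]))
        ll2 = mk_loglik(five_tip_tree, {k: v[0] for k, v in pairs.items()}, m1)
        ll2 += mk_loglik(five_tip_tree, {k: v[1] for k, v in pairs.items()}, m2)
        assert ll4 == pytest.approx(ll2, abs=1e-9)

    def test_dependent_with_tied_rates_equals_independent(self, five_tip_tree):
        pairs = {"A": (0, 0), "B": (0, 1), "C": (1, 0), "D": (1, 1), "E": (1, 1)}
        g1, l1, g2, l2 = 0.4, 0.9, 1.2, 0.6
        tied = dependent_generator([g2, g1, l2, g1, l1, g2, l1, l2])
        assert pagel_loglik(five_tip_tree, pairs, tied) == pytest.approx(
            pagel_loglik(five_tip_tree, pairs, independent_generator(g1, l1, g2, l2)),
            abs=1e-12,
        )

    def test_matches_four_state_brute_force(self, five_tip_tree):
        rng = np.random.default_rng(3)
        Q = dependent_generator(rng.uniform(0.2, 2.0, 8))
        pairs = {
            l: (int(rng.integers(2)), int(rng.integers(2)))
            for l in five_tip_tree.tip_labels
        }
        ll = pagel_loglik(five_tip_tree, pairs, Q)
        from songevo.phylo_core import linearize

        ta = linearize(five_tip_tree)
        m = MkModel(PAIR_STATES, Q)
        P = {
            i: transition_probability(m, float(ta.branch_lengths[i]))
            for i in range(ta.n_nodes - 1)
        }
        sidx = {s: i for i, s in enumerate(PAIR_STATES)}
        tipstate = {ta.tip_rows[l]: sidx[s] for l, s in pairs.items()}
        internal = [i for i in range(ta.n_nodes) if ta.children_index[i]]
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            st = dict(tipstate)
            st.update(dict(zip(internal, assign)))
            pr = 0.25
            for i in range(ta.n_nodes - 1):
                pr *= P[i][st[ta.parent_index[i]], st[i]]
            total += pr
        assert ll == pytest.approx(math.log(total), abs=1e-10)


class TestFitPair:
    def test_nesting_holds_on_every_run(self):
        tree = simulate_yule(60, seed=1)
        pairs, _ = simulate_dependent_pair(tree, [1.0] * 8, seed=1)
        res = fit_pagel_pair(tree, pairs, n_restarts=3, seed=0)
        for run in res.runs:
            assert run["ll_dependent"] >= run["ll_independent"] - 1e-6
        assert res.df == 4
        assert res.ll_dependent >= res.ll_independent - 1e-6

    def test_constant_trait_rejected(self):
        tree = simulate_yule(10, seed=2)
        pairs = {l: (0, i % 2) for i, l in enumerate(tree.tip_labels)}
        with pytest.raises(ValueError):
            fit_pagel_pair(tree, pairs, n_restarts=1, seed=0)

    def test_strong_dependence_detected(self):
        rates = {n: 1.0 for n in DEP_RATE_NAMES}
        rates["q_10_11"] = 10.0
        rates["q_01_00"] = 10.0
        tree = simulate_yule(100, seed=11)
        pairs, _ = simulate_dependent_pair(
            tree, [rates[n] for n in DEP_RATE_NAMES], seed=4
        )
        res = fit_pagel_pair(tree, pairs, n_restarts=2, seed=0)
        assert res.p_value < 0.05


class TestSweep:
    def _inputs(self, n=30, seed=5):
        tree = simulate_yule(n, seed=seed)
        pairs, _ = simulate_dependent_pair(tree, [1.0] * 8, seed=seed)
        learn = {l: ("stable" if a else "plastic") for l, (a, b) in pairs.items()}
        rng = np.random.default_rng(seed)
        vals = {l: float(rng.normal(2.0 + 2.0 * b, 0.7)) for l, (a, b) in pairs.items()}
        return tree, learn, vals

    def test_top_threshold_degenerate_so_u_minus_one_swept(self):
        tree, learn, vals = self._inputs()
        sweep = threshold_sweep(tree, learn, vals, runs_per_threshold=1, seed=0)
        u = len(set(vals.values()))
        assert sweep.thresholds.size == u - 1
        assert sweep.skipped_thresholds.size == 1

    def test_runs_per_threshold_records(self):
        tree, learn, vals = self._inputs(n=12, seed=6)
        sweep = threshold_sweep(tree, learn, vals, runs_per_threshold=3, seed=0)
        counts = {}
        for r in sweep.runs:
            counts[r["threshold"]] = counts.get(r["threshold"], 0) + 1
        assert set(counts.values()) == {3}

    def test_fixed_seed_reproducible_and_order_invariant(self):
        tree, learn, vals = self._inputs(n=12, seed=7)
        s1 = threshold_sweep(tree, learn, vals, runs_per_threshold=2, seed=3)
        shuffled_vals = dict(reversed(list(vals.items())))
        shuffled_learn = dict(reversed(list(learn.items())))
        s2 = threshold_sweep(tree, shuffled_learn, shuffled_vals, runs_per_threshold=2, seed=3)
        p1 = [r["p_value"] for r in s1.runs]
        p2 = [r["p_value"] for r in s2.runs]
        assert p1 == p2


class TestSummarize:
    def _sweep(self, n_thresholds, runs=2):
        rng = np.random.default_rng(0)
        thresholds = np.arange(n_thresholds, dtype=float)
        records = [
            {
                "threshold": float(t),
                "threshold_index": i,
                "run": r,
                "p_value": float(rng.uniform()),
                "dependent_rates": rng.uniform(0, 2, 8),
            }
            for i, t in enumerate(thresholds)
            for r in range(runs)
        ]
        from songevo.pagel_sweep import SweepResult

        return SweepResult(thresholds=thresholds, runs=records, skipped_thresholds=np.array([]))

    def test_even_split_9_into_3(self):
        assert _bin_sizes(9, 3) == [3, 3, 3]

    def test_remainder_goes_to_lower_bins(self):
        assert _bin_sizes(10, 3) == [4, 3, 3]
        assert _bin_sizes(11, 5) == [3, 2, 2, 2, 2]

    def test_bin_means_are_convex_combinations(self):
        sweep = self._sweep(9)
        bins = summarize_sweep(sweep, n_bins=3, n_boot=100, seed=0)
        for b in bins:
            member = {i for i, t in enumerate(sweep.thresholds) if t in b["thresholds"]}
            rates = np.array(
                [r["dependent_rates"] for r in sweep.runs if r["threshold_index"] in member]
            )
            for j, name in enumerate(DEP_RATE_NAMES):
                assert rates[:, j].min() - 1e-12 <= b["mean_rates"][name] <= rates[:, j].max() + 1e-12
            assert 0.0 <= b["percent_significant"] <= 100.0

    def test_more_bins_than_thresholds_rejected(self):
        with pytest.raises(ValueError):
            summarize_sweep(self._sweep(3), n_bins=4)


class TestBinaryRuns:
    def test_run_count_and_summary_fields(self):
        tree = simulate_yule(40, seed=9)
        pairs, _ = simulate_dependent_pair(tree, [1.0] * 8, seed=9)
        learn = {l: ("stable" if a else "plastic") for l, (a, b) in pairs.items()}
        mating = {l: ("mono" if b else "poly") for l, (a, b) in pairs.items()}
        res = run_pagel_binary(tree, learn, mating, runs=5, seed=0)
        assert res["n_runs"] == 5 and len(res["runs"]) == 5
        assert 0.0 <= res["percent_significant"] <= 100.0
        assert set(res["mean_rates"]) == set(DEP_RATE_NAMES)

    def test_constant_trait_rejected(self):
        tree = simulate_yule(10, seed=3)
        learn = {l: "stable" for l in tree.tip_labels}
        mating = {l: "mono" for l in tree.tip_labels}
        with pytest.raises(ValueError):
            run_pagel_binary(tree, learn, mating, runs=2, seed=0)
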