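"""Pagel's correlated-evolution test for binary trait pairs, with an
exhaustive threshold sweep over a continuous trait.

Two binary traits are modelled jointly on the combined state space
{(0,0), (0,1), (1,0), (1,1)}.  The *dependent* model has eight free
transition rates (each single-trait gain/loss rate may differ with the
state of the other trait); simultaneous changes of both traits are
structural zeros.  The *independent* model constrains the chain to the
product of two 2-state chains (four free rates), so its log-likelihood
equals the sum of the two separate Mk log-likelihoods.  The models are
compared by a likelihood-ratio test with 4 degrees of freedom.

The threshold sweep re-runs this test with a continuous song trait
binarized at every observed (non-degenerate) value; each "run" is one
random-restart maximum-likelihood attempt, emulating the run-to-run
variability of repeated optimizer launches.  Per-bin summaries average
the eight dependent-model rates and the percent of runs significant at
p < 0.05 across contiguous thirds (or halves/quarters/fifths) of the
sorted unique threshold values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .mk_ctmc import MkModel, _branch_P, _pruning, _rate_scale, _tip_partials
from .phylo_core import Phylogeny, TreeArrays, linearize
from .trait_model import binarize_by_threshold

__all__ = [
    "PAIR_STATES",
    "DEP_RATE_NAMES",
    "dependent_generator",
    "independent_generator",
    "pagel_loglik",
    "fit_pagel_pair",
    "PagelPairResult",
    "threshold_sweep",
    "SweepResult",
    "summarize_sweep",
    "run_pagel_binary",
]

#: Combined states, trait order (trait1, trait2); 0 = first level, 1 = second.
PAIR_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

#: The eight dependent-model rates, keyed as q_<from><to> over PAIR_STATES
#: indices written as bit pairs: e.g. "q_00_10" is trait1 gain while
#: trait2 is 0.
DEP_RATE_NAMES = (
    "q_00_01",  # trait2 gain | trait1=0
    "q_00_10",  # trait1 gain | trait2=0
    "q_01_00",  # trait2 loss | trait1=0
    "q_01_11",  # trait1 gain | trait2=1
    "q_10_00",  # trait1 loss | trait2=0
    "q_10_11",  # trait2 gain | trait1=1
    "q_11_01",  # trait1 loss | trait2=1
    "q_11_10",  # trait2 loss | trait1=1
)

_DEP_EDGES = (
    (0, 1),
    (0, 2),
    (1, 0),
    (1, 3),
    (2, 0),
    (2, 3),
    (3, 1),
    (3, 2),
)


def dependent_generator(rates8: Sequence[float]) -> np.ndarray:
    """4-state generator from the eight single-change rates.

    Dual transitions (both traits changing at once: 00<->11, 01<->10)
    are structural zeros.
    """
    rates8 = np.asarray(rates8, dtype=float)
    if rates8.size != 8:
        raise ValueError("need exactly 8 rates")
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(rates8, _DEP_EDGES):
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def independent_generator(
    gain1: float, loss1: float, gain2: float, loss2: float
) -> np.ndarray:
    """4-state generator of two independent 2-state chains.

    The trait1 gain/loss rates do not depend on trait2's state and vice
    versa: the induced dependent-model rate vector has its four pairs of
    entries equal.
    """
    return dependent_generator(
        [gain2, gain1, loss2, gain1, loss1, gain2, loss1, loss2]
    )


@dataclass
class PagelPairResult:
    """Dependent-vs-independent fit of one binary trait pair."""

    ll_independent: float
    ll_dependent: float
    statistic: float
    df: int
    p_value: float
    independent_rates: np.ndarray  # (gain1, loss1, gain2, loss2)
    dependent_rates: np.ndarray  # aligned with DEP_RATE_NAMES
    runs: list = field(default_factory=list)  # per-run records


@dataclass
class SweepResult:
    """Per-threshold Pagel runs over a continuous trait."""

    thresholds: np.ndarray  # swept (non-degenerate) thresholds, ascending
    runs: list  # list of dict records (threshold, run, rates, LLs, p)
    skipped_thresholds: np.ndarray
    trait: str | None = None
    seed: int | None = None


# ----------------------------------------------------------------------
# likelihoods
# ----------------------------------------------------------------------

def _pair_tip_states(
    paired: Mapping[str, tuple],
) -> dict[str, tuple]:
    out = {}
    for lab, pair in paired.items():
        if pair is None:
            continue
        a, b = pair
        if a is None or b is None:
            continue
        a, b = int(a), int(b)
        if a not in (0, 1) or b not in (0, 1):
            raise ValueError(f"tip {lab!r}: states must be binary, got {pair!r}")
        out[lab] = (a, b)
    return out


def pagel_loglik(
    tree: Phylogeny | TreeArrays,
    paired_tip_states: Mapping[str, tuple],
    Q: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> float:
    """Pruning log-likelihood of paired binary tips on the 4-state chain."""
    model = MkModel(PAIR_STATES, Q, root_prior)
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    tips = _pair_tip_states(paired_tip_states)
    P = _branch_P(ta, model.Q)
    tipL = _tip_partials(ta, tips, model.states)
    ll, _, _ = _pruning(ta, P, tipL, model.root_prior)
    return ll


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _fit_generic(
    ta: TreeArrays,
    tipL: np.ndarray,
    prior: np.ndarray,
    build_Q,
    n_par: int,
    x0: np.ndarray,
    bounds,
) -> optimize.OptimizeResult:
    def nll(log_rates: np.ndarray) -> float:
        P = _branch_P(ta, build_Q(np.exp(log_rates)))
        ll, _, _ = _pruning(ta, P, tipL, prior)
        return 1e10 if not np.isfinite(ll) else -ll

    return optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-10}
    )


def fit_pagel_pair(
    tree: Phylogeny | TreeArrays,
    paired_tip_states: Mapping[str, tuple],
    n_restarts: int = 3,
    seed: int | None = 0,
) -> PagelPairResult:
    """ML fits of the dependent and independent models plus the LR test.

    Each restart draws fresh log-uniform starting rates over
    [1e-3, 1e2] per unit mean tree depth and is recorded as one "run";
    the reported fit is the best run.  The dependent model can never fit
    worse than the independent one (nesting); this is asserted up to
    optimizer tolerance.
    """
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    tips = _pair_tip_states(paired_tip_states)
    t1 = {v[0] for v in tips.values()}
    t2 = {v[1] for v in tips.values()}
    if len(t1) < 2 or len(t2) < 2:
        raise ValueError("both traits must vary across the tips")
    from .mk_ctmc import ard_generator

    prior = np.full(4, 0.25)
    prior2 = np.full(2, 0.5)
    tipL = _tip_partials(ta, tips, PAIR_STATES)
    tipL1 = _tip_partials(ta, {l: v[0] for l, v in tips.items()}, (0, 1))
    tipL2 = _tip_partials(ta, {l: v[1] for l, v in tips.items()}, (0, 1))
    scale = _rate_scale(ta)
    lo, hi = math.log(1e-3 * scale), math.log(1e2 * scale)
    bounds2 = [(lo - 12.0, hi + 3.0)] * 2
    rng = np.random.default_rng(seed)

    runs = []
    best_dep = best_ind = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            x0_ind = np.full(4, math.log(scale))
            x0_dep = np.full(8, math.log(scale))
        else:
            x0_ind = rng.uniform(lo, hi, size=4)
            x0_dep = rng.uniform(lo, hi, size=8)
        # The independent model is separable: its ML is the sum of two
        # 2-state fits, one per trait.
        res1 = _fit_generic(
            ta, tipL1, prior2, lambda q: ard_generator(2, q), 2,
            x0_ind[:2], bounds2,
        )
        res2 = _fit_generic(
            ta, tipL2, prior2, lambda q: ard_generator(2, q), 2,
            x0_ind[2:], bounds2,
        )
        ll_ind = -float(res1.fun) - float(res2.fun)
        ind_rates = np.concatenate([np.exp(res1.x), np.exp(res2.x)])
        res_dep = _fit_generic(
            ta,
            tipL,
            prior,
            dependent_generator,
            8,
            x0_dep,
            [(lo - 12.0, hi + 3.0)] * 8,
        )
        ll_dep = -float(res_dep.fun)
        # nesting repair: seed the dependent fit from the independent one
        if ll_dep < ll_ind - 1e-6:
            g1, l1, g2, l2 = ind_rates
            x0_fix = np.log(
                np.maximum([g2, g1, l2, g1, l1, g2, l1, l2], 1e-300)
            )
            res_fix = _fit_generic(
                ta,
                tipL,
                prior,
                dependent_generator,
                8,
                x0_fix,
                [(lo - 12.0, hi + 3.0)] * 8,
            )
            if -float(res_fix.fun) > ll_dep:
                res_dep = res_fix
                ll_dep = -float(res_fix.fun)
        stat = max(0.0, 2.0 * (ll_dep - ll_ind))
        p = float(stats.chi2.sf(stat, 4))
        runs.append(
            {
                "run": r,
                "ll_independent": ll_ind,
                "ll_dependent": ll_dep,
                "statistic": stat,
                "p_value": p,
                "independent_rates": ind_rates,
                "dependent_rates": np.exp(res_dep.x),
            }
        )
        if best_ind is None or ll_ind > best_ind[0]:
            best_ind = (ll_ind, ind_rates)
        if best_dep is None or ll_dep > best_dep[0]:
            best_dep = (ll_dep, np.exp(res_dep.x))

    ll_ind, rates_ind = best_ind
    ll_dep, rates_dep = best_dep
    if ll_dep < ll_ind - 1e-6:
        raise AssertionError(
            "dependent model fit worse than nested independent model"
        )
    ll_dep = max(ll_dep, ll_ind)
    stat = 2.0 * (ll_dep - ll_ind)
    return PagelPairResult(
        ll_independent=ll_ind,
        ll_dependent=ll_dep,
        statistic=stat,
        df=4,
        p_value=float(stats.chi2.sf(stat, 4)),
        independent_rates=rates_ind,
        dependent_rates=rates_dep,
        runs=runs,
    )


# ----------------------------------------------------------------------
# threshold sweep
# ----------------------------------------------------------------------

def threshold_sweep(
    tree: Phylogeny | TreeArrays,
    learning_states: Mapping[str, object],
    trait_values: Mapping[str, float],
    runs_per_threshold: int = 100,
    seed: int | None = 0,
    trait_name: str | None = None,
) -> SweepResult:
    """Pagel test at every unique observed value of a continuous trait.

    Tips need both a learning state and a trait value; the trait is
    binarized high/low at each unique value (strictly-greater = high).
    Degenerate thresholds (an empty class) are skipped and reported.
    Run seeds derive from (threshold index, run index), so results are
    invariant to species input order.
    """
    if runs_per_threshold < 1:
        raise ValueError("runs_per_threshold must be >= 1")
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    labels = [
        l
        for l in ta.tip_labels
        if learning_states.get(l) is not None and trait_values.get(l) is not None
    ]
    learn = {l: learning_states[l] for l in labels}
    lv = sorted({str(v) for v in learn.values()})
    if len(lv) != 2:
        raise ValueError(f"learning states must be binary, got {lv}")
    learn01 = {l: lv.index(str(learn[l])) for l in labels}
    vals = {l: float(trait_values[l]) for l in labels}
    sub = prune_labels(ta, labels)
    uniq = np.unique(np.array(list(vals.values())))

    swept = []
    skipped = []
    run_records = []
    ss = np.random.SeedSequence(seed)
    for ti, thr in enumerate(uniq):
        labels01, degenerate = binarize_by_threshold(vals, float(thr))
        if degenerate:
            skipped.append(float(thr))
            continue
        swept.append(float(thr))
        paired = {
            l: (learn01[l], 1 if labels01[l] == "high" else 0) for l in labels
        }
        for run in range(runs_per_threshold):
            run_seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(ti, run)
                ).generate_state(1)[0]
                % (2**31)
            )
            res = fit_pagel_pair(sub, paired, n_restarts=1, seed=run_seed)
            rec = res.runs[0]
            run_records.append(
                {
                    "threshold": float(thr),
                    "threshold_index": len(swept) - 1,
                    "run": run,
                    "seed": run_seed,
                    "ll_independent": rec["ll_independent"],
                    "ll_dependent": rec["ll_dependent"],
                    "p_value": rec["p_value"],
                    "dependent_rates": rec["dependent_rates"],
                }
            )
    return SweepResult(
        thresholds=np.asarray(swept),
        runs=run_records,
        skipped_thresholds=np.asarray(skipped),
        trait=trait_name,
        seed=seed,
    )


def _bin_sizes(n: int, n_bins: int) -> list[int]:
    """Contiguous bin sizes; remainder thresholds go to the lower bins."""
    base = n // n_bins
    rem = n % n_bins
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def summarize_sweep(
    sweep: SweepResult,
    n_bins: int = 3,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> list[dict]:
    """Bin the sweep into contiguous threshold groups and summarize.

    For each bin: the mean of each of the eight dependent-model rates
    across all runs of all member thresholds, a 95% percentile-bootstrap
    CI on each mean, and the mean percent of runs significant at
    ``alpha``.
    """
    if n_bins not in (2, 3, 4, 5):
        raise ValueError("n_bins must be between 2 and 5")
    n_thr = sweep.thresholds.size
    if n_bins > n_thr:
        raise ValueError("more bins than thresholds")
    sizes = _bin_sizes(n_thr, n_bins)
    edges = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    out = []
    for b in range(n_bins):
        members = range(edges[b], edges[b + 1])
        member_set = set(members)
        recs = [r for r in sweep.runs if r["threshold_index"] in member_set]
        rates = np.array([r["dependent_rates"] for r in recs])
        pvals = np.array([r["p_value"] for r in recs])
        mean_rates = rates.mean(axis=0)
        boot_idx = rng.integers(0, len(recs), size=(n_boot, len(recs)))
        boot_means = rates[boot_idx].mean(axis=1)
        ci_lo = np.percentile(boot_means, 2.5, axis=0)
        ci_hi = np.percentile(boot_means, 97.5, axis=0)
        # percent significant per threshold, then averaged across thresholds
        pct_by_thr = []
        for ti in members:
            pv = np.array(
                [r["p_value"] for r in recs if r["threshold_index"] == ti]
            )
            pct_by_thr.append(100.0 * float(np.mean(pv < alpha)))
        out.append(
            {
                "bin": b,
                "thresholds": sweep.thresholds[edges[b] : edges[b + 1]],
                "n_runs": len(recs),
                "mean_rates": dict(zip(DEP_RATE_NAMES, mean_rates)),
                "ci_low": dict(zip(DEP_RATE_NAMES, ci_lo)),
                "ci_high": dict(zip(DEP_RATE_NAMES, ci_hi)),
                "percent_significant": float(np.mean(pct_by_thr)),
                "mean_p": float(pvals.mean()),
            }
        )
    return out


def run_pagel_binary(
    tree: Phylogeny | TreeArrays,
    learning_states: Mapping[str, object],
    binary_trait: Mapping[str, object],
    runs: int = 1000,
    seed: int | None = 0,
) -> dict:
    """Repeated-run Pagel test of learning state against a binary trait
    (social mating system or EPP class).

    Species missing either trait are dropped; each run is an independent
    random-restart fit.  Reports the per-run records, the percent of
    runs significant at p < 0.05, and the mean dependent rates.
    """
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    labels = [
        l
        for l in ta.tip_labels
        if learning_states.get(l) is not None and binary_trait.get(l) is not None
    ]
    lv1 = sorted({str(learning_states[l]) for l in labels})
    lv2 = sorted({str(binary_trait[l]) for l in labels})
    if len(lv1) != 2 or len(lv2) != 2:
        raise ValueError(
            f"both traits must be binary and vary: got {lv1} and {lv2}"
        )
    paired = {
        l: (lv1.index(str(learning_states[l])), lv2.index(str(binary_trait[l])))
        for l in labels
    }
    sub = prune_labels(ta, labels)
    ss = np.random.SeedSequence(seed)
    records = []
    for run in range(runs):
        run_seed = int(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(run,))
            .generate_state(1)[0]
            % (2**31)
        )
        res = fit_pagel_pair(sub, paired, n_restarts=1, seed=run_seed)
        rec = res.runs[0]
        rec["run"] = run
        records.append(rec)
    pvals = np.array([r["p_value"] for r in records])
    rates = np.array([r["dependent_rates"] for r in records])
    return {
        "runs": records,
        "n_runs": runs,
        "trait_levels": (lv1, lv2),
        "percent_significant": 100.0 * float(np.mean(pvals < 0.05)),
        "mean_rates": dict(zip(DEP_RATE_NAMES, rates.mean(axis=0))),
        "mean_p": float(pvals.mean()),
    }


def prune_labels(ta: TreeArrays, labels: Sequence[str]) -> TreeArrays:
    """Restrict the working tree to ``labels`` (no-op if already equal)."""
    from .phylo_core import prune_to_taxa

    if set(labels) == set(ta.tip_labels):
        return ta
    return linearize(prune_to_taxa(ta.tree, set(labels)))
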