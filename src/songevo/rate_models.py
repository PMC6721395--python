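"""Brownian-motion likelihoods with one or state-dependent rates.

The single-rate model treats the tip values of a continuous trait as a
multivariate normal draw with mean ``mu * 1`` and covariance
``sigma2 * C`` where ``C`` is the phylogenetic covariance (shared
root-to-tip path lengths).  The multi-rate ("censored rate" / Brownie)
model lets the diffusion rate differ between character-state regimes
painted on the branches by a stochastic character map:

    V = sum_r sigma2_r * C_r,

where ``C_r[i, j]`` is the branch length shared by tips i and j that was
spent in regime r.  The ensemble test fits the multi-rate model on each
of many sampled maps, averages the log-likelihoods, and compares the
mean against the (map-independent) single-rate log-likelihood with a
chi-square test on 2 * (mean LL_multi - LL_single) with
df = (#regimes - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import optimize, stats

from .mk_ctmc import StateMap
from .phylo_core import Phylogeny, TreeArrays, linearize

__all__ = [
    "BrownieFit",
    "EnsembleRateTest",
    "bm_loglik",
    "fit_bm",
    "regime_covariances",
    "fit_bm_multirate",
    "chi_square_compare",
    "ensemble_rate_test",
]


@dataclass
class BrownieFit:
    """Fitted Brownian model: per-regime rates, root state, likelihood."""

    regimes: tuple
    sigma2: np.ndarray  # one entry per regime
    root_state: float
    log_likelihood: float
    dropped_regimes: tuple = ()
    diagnostics: dict = field(default_factory=dict)


@dataclass
class EnsembleRateTest:
    """Brownie-style ensemble comparison over a stochastic-map ensemble."""

    ll_simple: float
    ll_complex_mean: float
    df: int
    statistic: float
    p_value: float
    per_map_sigma2: np.ndarray  # (n_maps, n_regimes)
    per_map_ll: np.ndarray
    regimes: tuple
    n_failed: int = 0


# ----------------------------------------------------------------------
# single rate
# ----------------------------------------------------------------------

def _chol_quad(V: np.ndarray, x: np.ndarray, ones: np.ndarray):
    """Cholesky pieces for a GLS fit: logdet, whitened x and 1 vectors."""
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    sol = sla.solve_triangular(
        L, np.column_stack([x, ones]), lower=True, check_finite=False
    )
    return logdet, sol[:, 0], sol[:, 1]


def bm_loglik(
    C: np.ndarray, values: np.ndarray, sigma2: float, root_state: float
) -> float:
    """Log density of tip values under single-rate BM.

    ``C`` is the phylogenetic covariance of the tips in the same order
    as ``values``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    x = np.asarray(values, dtype=float) - root_state
    n = x.size
    V = sigma2 * C
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    q = float(np.linalg.solve(L, x) @ np.linalg.solve(L, x))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + q)


def fit_bm(C: np.ndarray, values: np.ndarray) -> BrownieFit:
    """Closed-form ML single-rate fit.

    The root state is the GLS phylogenetic mean and the rate uses the
    ML (1/n) denominator:

        mu  = (1' C^-1 x) / (1' C^-1 1)
        s2  = (x - mu 1)' C^-1 (x - mu 1) / n
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 tips")
    ones = np.ones(n)
    logdetC, sx, s1 = _chol_quad(C, x, ones)
    mu = float(s1 @ sx) / float(s1 @ s1)
    r = sx - mu * s1
    s2 = float(r @ r) / n
    if s2 <= 0 or not np.isfinite(s2):
        warnings.warn("zero trait variance: rate at the 0 boundary")
        s2 = np.finfo(float).tiny
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdetC + n)
    return BrownieFit(
        regimes=("all",),
        sigma2=np.array([s2]),
        root_state=mu,
        log_likelihood=float(ll),
    )


# ----------------------------------------------------------------------
# regime-painted rates
# ----------------------------------------------------------------------

def regime_covariances(
    ta: TreeArrays,
    state_map: StateMap,
    regime_of_state: Mapping[object, object],
    tip_order: Sequence[str],
) -> tuple[np.ndarray, tuple]:
    """Per-regime shared-path covariance components.

    ``regime_of_state`` maps each character state (as named in the map)
    to a regime label; states mapped to the same label share a rate.
    Returns an array of shape (n_regimes, n_tips, n_tips) in the order
    of the sorted distinct regime labels, restricted to ``tip_order``.
    """
    regimes = tuple(sorted(set(regime_of_state.values()), key=str))
    reg_idx = {r: i for i, r in enumerate(regimes)}
    tip_pos = {lab: j for j, lab in enumerate(ta.tip_labels)}
    keep_cols = np.array([tip_pos[lab] for lab in tip_order])
    nb = ta.n_nodes - 1
    w = np.zeros((len(regimes), nb))
    for i in ta.nonroot():
        nid = ta.order[i]
        for s_idx, dur in state_map.segments[nid]:
            state = state_map.states[s_idx]
            w[reg_idx[regime_of_state[state]], i] += dur
    D = ta.desc_mask[:nb][:, keep_cols].astype(float)  # (nb, n_keep)
    C = np.stack([(D * wr[:, None]).T @ D for wr in w])
    return C, regimes


def fit_bm_multirate(
    C_regimes: np.ndarray,
    values: np.ndarray,
    regimes: tuple,
    restarts: int = 2,
    seed: int | None = 0,
) -> BrownieFit:
    """ML fit of state-dependent rates given regime covariance pieces.

    Regimes with zero total mapped branch length are dropped with a
    warning (the model reduces).  The root state is profiled out by GLS
    at each candidate rate vector.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    ones = np.ones(n)
    total = np.array([np.trace(Ci) for Ci in C_regimes])
    active = total > 1e-14
    dropped = tuple(r for r, a in zip(regimes, active) if not a)
    if dropped:
        warnings.warn(f"regimes with zero mapped length dropped: {dropped}")
    Cs = C_regimes[active]
    act_regimes = tuple(r for r, a in zip(regimes, active) if a)
    m = Cs.shape[0]

    # The overall scale profiles out in closed form (as in fit_bm), so
    # only the m-1 log rate ratios relative to the first regime are
    # optimized numerically.
    def profiled(log_ratio: np.ndarray):
        u = np.concatenate([[1.0], np.exp(log_ratio)])
        V0 = np.tensordot(u, Cs, axes=1)
        try:
            logdet0, sx, s1 = _chol_quad(V0, x, ones)
        except np.linalg.LinAlgError:
            return 1e10, None
        mu = float(s1 @ sx) / float(s1 @ s1)
        r = sx - mu * s1
        s = float(r @ r) / n
        if s <= 0 or not np.isfinite(s):
            return 1e10, None
        nll = 0.5 * (n * np.log(2 * np.pi) + n * np.log(s) + logdet0 + n)
        return nll, (s * u, mu)

    if m == 1:
        best_fun, (s2, mu) = profiled(np.zeros(0))
        success = True
    elif m == 2:
        res = optimize.minimize_scalar(
            lambda z: profiled(np.array([z]))[0],
            bounds=(-18.0, 18.0),
            method="bounded",
            options={"xatol": 1e-9},
        )
        best_fun, parts = profiled(np.array([res.x]))
        s2, mu = parts
        success = bool(res.success)
    else:
        rng = np.random.default_rng(seed)
        starts = [np.zeros(m - 1)]
        for _ in range(max(0, restarts - 1)):
            starts.append(rng.uniform(-3.0, 3.0, size=m - 1))
        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda z: profiled(z)[0],
                x0,
                method="L-BFGS-B",
                bounds=[(-18.0, 18.0)] * (m - 1),
                options={"ftol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        best_fun, parts = profiled(best.x)
        s2, mu = parts
        success = bool(best.success)
    ll = -float(best_fun)
    full_s2 = np.full(len(regimes), np.nan)
    full_s2[active] = s2
    return BrownieFit(
        regimes=regimes,
        sigma2=full_s2,
        root_state=mu,
        log_likelihood=ll,
        dropped_regimes=dropped,
        diagnostics={"active_regimes": act_regimes, "converged": success},
    )


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------

def chi_square_compare(ll_simple: float, ll_complex: float, df: int) -> float:
    """Upper-tail chi-square p for 2 * (ll_complex - ll_simple).

    Negative statistics (possible from ensemble averaging noise) are
    clipped to zero with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (ll_complex - ll_simple)
    if stat < 0:
        if stat < -1e-8:
            warnings.warn("negative likelihood-ratio statistic clipped to 0")
        stat = 0.0
    return float(stats.chi2.sf(stat, df))


def ensemble_rate_test(
    tree: Phylogeny | TreeArrays,
    tip_values: Mapping[str, float],
    map_ensemble: Sequence[StateMap],
    regime_of_state: Mapping[object, object],
    restarts: int = 2,
    seed: int | None = 0,
) -> EnsembleRateTest:
    """Brownie ensemble test of state-dependent vs single-rate BM.

    The multi-rate model is fitted on every stochastic map; the mean of
    the per-map log-likelihoods is compared against the single-rate
    log-likelihood (computed once, it does not depend on the painting)
    with df = #regimes - 1.  Per-map rate vectors are retained for
    rate-distribution summaries.
    """
    if not map_ensemble:
        raise ValueError("empty map ensemble")
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    labels = [l for l in ta.tip_labels if l in tip_values and tip_values[l] is not None]
    x = np.array([float(tip_values[l]) for l in labels])
    # single-rate fit on the plain covariance restricted to observed tips
    C_all, regs0 = regime_covariances(
        ta, map_ensemble[0], {s: "all" for s in map_ensemble[0].states}, labels
    )
    simple = fit_bm(C_all[0], x)
    regimes = tuple(sorted(set(regime_of_state.values()), key=str))
    n_reg = len(regimes)
    per_ll = []
    per_s2 = []
    n_failed = 0
    for j, sm in enumerate(map_ensemble):
        Cs, regs = regime_covariances(ta, sm, regime_of_state, labels)
        try:
            fitr = fit_bm_multirate(
                Cs, x, regs, restarts=restarts,
                seed=None if seed is None else seed + j,
            )
        except (np.linalg.LinAlgError, RuntimeError):
            n_failed += 1
            continue
        per_ll.append(fitr.log_likelihood)
        per_s2.append(fitr.sigma2)
    if n_failed > 0.05 * len(map_ensemble):
        raise RuntimeError(f"{n_failed} multi-rate fits failed (> 5% of ensemble)")
    per_ll = np.asarray(per_ll)
    per_s2 = np.asarray(per_s2)
    mean_ll = float(per_ll.mean())
    df = max(n_reg - 1, 1)
    p = chi_square_compare(simple.log_likelihood, mean_ll, df)
    stat = max(0.0, 2.0 * (mean_ll - simple.log_likelihood))
    return EnsembleRateTest(
        ll_simple=simple.log_likelihood,
        ll_complex_mean=mean_ll,
        df=df,
        statistic=stat,
        p_value=p,
        per_map_sigma2=per_s2,
        per_map_ll=per_ll,
        regimes=regimes,
        n_failed=n_failed,
    )
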