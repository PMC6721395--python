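"""Discrete-trait continuous-time Markov (Mk) models on phylogenies.

Provides the pruning (Felsenstein) log-likelihood for a k-state CTMC,
maximum-likelihood fitting of equal-rates (ER) and all-rates-different
(ARD) generators, marginal ancestral-state probabilities, stochastic
character mapping (endpoint-conditioned path sampling by uniformization),
and transition counting over mapped histories.

The generator ``Q`` is a k x k matrix with non-negative off-diagonals and
zero row sums; ``Q[i, j]`` is the instantaneous rate of an i -> j change.
The root state carries a prior, uniform by default (configurable to the
fitted stationary distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .phylo_core import Phylogeny, TreeArrays, linearize

__all__ = [
    "MkModel",
    "MkFit",
    "StateMap",
    "er_generator",
    "ard_generator",
    "transition_probability",
    "mk_loglik",
    "fit_mk",
    "lrt_er_vs_ard",
    "ancestral_marginals",
    "sample_stochastic_maps",
    "count_transitions",
    "minimum_transitions",
    "er_profile_ci",
]

NEG_INF = float("-inf")


@dataclass
class MkModel:
    """A k-state Markov generator with a root prior."""

    states: tuple
    Q: np.ndarray
    root_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match state count")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if np.abs(self.Q.sum(axis=1)).max() > 1e-12 * max(1.0, np.abs(self.Q).max()):
            raise ValueError("rows of Q must sum to 0")
        if self.root_prior is None:
            self.root_prior = np.full(k, 1.0 / k)
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if abs(self.root_prior.sum() - 1.0) > 1e-9:
                raise ValueError("root prior must sum to 1")

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass
class MkFit:
    """A fitted Mk model with optimizer diagnostics."""

    model: MkModel
    log_likelihood: float
    family: str
    rates: np.ndarray
    n_restarts: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass
class StateMap:
    """One sampled character history ("painted" tree).

    ``segments[node]`` lists ``(state_index, duration)`` pairs along the
    branch *above* ``node``, ordered from the parent end to the child
    end; durations sum to the branch length and adjacent segments differ
    in state.  ``node_states`` holds the state index at every node.
    """

    states: tuple
    segments: dict[int, list[tuple[int, float]]]
    node_states: dict[int, int]


def er_generator(k: int, rate: float) -> np.ndarray:
    Q = np.full((k, k), rate, dtype=float)
    np.fill_diagonal(Q, -(k - 1) * rate)
    return Q


def ard_generator(k: int, rates: Sequence[float]) -> np.ndarray:
    """Build a generator from k*(k-1) off-diagonal rates in row-major order."""
    rates = np.asarray(rates, dtype=float)
    if rates.size != k * (k - 1):
        raise ValueError("need k*(k-1) rates")
    Q = np.zeros((k, k))
    pos = 0
    for i in range(k):
        for j in range(k):
            if i != j:
                Q[i, j] = rates[pos]
                pos += 1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ----------------------------------------------------------------------
# transition probabilities
# ----------------------------------------------------------------------

def transition_probability(model: MkModel, t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to one."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return _expm_many(model.Q, np.array([t]))[0]


def _expm_many(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for a vector of times, via one eigendecomposition.

    Falls back to per-time ``scipy.linalg.expm`` if Q is numerically
    defective.
    """
    k = Q.shape[0]
    ts = np.asarray(ts, dtype=float)
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        cond = np.abs(U).sum(axis=0).max() * np.abs(Uinv).sum(axis=0).max()
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        E = np.exp(np.outer(ts, lam))  # (m, k)
        P = np.einsum("ij,mj,jl->mil", U, E, Uinv)
        P = np.real(P)
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * t) for t in ts])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


# ----------------------------------------------------------------------
# pruning likelihood
# ----------------------------------------------------------------------

def _tip_partials(
    ta: TreeArrays, tip_states: Mapping[str, object], states: Sequence
) -> np.ndarray:
    """Indicator partials at tips; tips absent from ``tip_states`` are
    treated as missing (all-ones row)."""
    k = len(states)
    state_idx = {s: i for i, s in enumerate(states)}
    L = np.ones((ta.n_nodes, k))
    for lab, row in ta.tip_rows.items():
        if lab in tip_states and tip_states[lab] is not None:
            s = tip_states[lab]
            if s not in state_idx:
                raise ValueError(f"tip {lab!r} has state {s!r} not in model states")
            L[row] = 0.0
            L[row, state_idx[s]] = 1.0
    return L


def _pruning(
    ta: TreeArrays, P: np.ndarray, tipL: np.ndarray, prior: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Postorder pass.  Returns (loglik, scaled partials, log scale sum).

    ``P[i]`` is the transition matrix for the branch above node ``i``
    (unused for the root row).
    """
    L = tipL.copy()
    logscale = 0.0
    for nodes, childs, starts in ta.levels:
        M = np.einsum("nij,nj->ni", P[childs], L[childs])
        acc = np.multiply.reduceat(M, starts, axis=0)
        mx = acc.max(axis=1)
        if (mx <= 0.0).any():
            return NEG_INF, L, logscale
        acc /= mx[:, None]
        logscale += float(np.log(mx).sum())
        L[nodes] = acc
    lik = float(prior @ L[ta.root_index])
    if lik <= 0.0:
        return NEG_INF, L, logscale
    return math.log(lik) + logscale, L, logscale


def mk_loglik(
    tree: Phylogeny | TreeArrays,
    tip_states: Mapping[str, object],
    model: MkModel,
) -> float:
    """Felsenstein pruning log-likelihood of tip states under ``model``."""
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    P = _branch_P(ta, model.Q)
    tipL = _tip_partials(ta, tip_states, model.states)
    ll, _, _ = _pruning(ta, P, tipL, model.root_prior)
    return ll


def _branch_P(ta: TreeArrays, Q: np.ndarray) -> np.ndarray:
    """Per-node transition matrices for the branch above each node."""
    n, k = ta.n_nodes, Q.shape[0]
    P = np.zeros((n, k, k))
    nr = ta.nonroot()
    P[nr] = _expm_many(Q, ta.branch_lengths[nr])
    P[ta.root_index] = np.eye(k)
    return P


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _rate_scale(ta: TreeArrays) -> float:
    """1 / (mean root-to-tip depth): rates are searched per unit depth."""
    depths = ta.desc_mask[ta.nonroot()].T @ np.nan_to_num(
        ta.branch_lengths[ta.nonroot()]
    )
    mean_depth = float(depths.mean()) if depths.size else 1.0
    return 1.0 / max(mean_depth, 1e-12)


def fit_mk(
    tree: Phylogeny | TreeArrays,
    tip_states: Mapping[str, object],
    family: str = "ER",
    restarts: int = 10,
    seed: int | None = 0,
    states: Sequence | None = None,
    root_prior: np.ndarray | None = None,
) -> MkFit:
    """Maximum-likelihood Mk fit by bounded multi-start optimization.

    ``family`` is ``"ER"`` (one symmetric rate), ``"SYM"`` (one rate per
    unordered pair) or ``"ARD"`` (one rate per ordered pair).  Rates are
    optimized on a log scale; starts are drawn log-uniformly over
    [1e-4, 1e2] per unit mean tree depth.
    """
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    if states is None:
        observed = {
            tip_states[l]
            for l in ta.tip_labels
            if l in tip_states and tip_states[l] is not None
        }
        states = tuple(sorted(observed, key=str))
    states = tuple(states)
    k = len(states)
    if k < 2:
        raise ValueError("need at least 2 distinct states")
    family = family.upper()
    if family == "ER":
        n_par = 1
    elif family == "SYM":
        n_par = k * (k - 1) // 2
    elif family == "ARD":
        n_par = k * (k - 1)
    else:
        raise ValueError(f"unknown model family {family!r}")

    tipL = _tip_partials(ta, tip_states, states)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)

    def build_Q(log_rates: np.ndarray) -> np.ndarray:
        r = np.exp(log_rates)
        if family == "ER":
            return er_generator(k, float(r[0]))
        if family == "SYM":
            Q = np.zeros((k, k))
            pos = 0
            for i in range(k):
                for j in range(i + 1, k):
                    Q[i, j] = Q[j, i] = r[pos]
                    pos += 1
            np.fill_diagonal(Q, -Q.sum(axis=1))
            return Q
        return ard_generator(k, r)

    def nll(log_rates: np.ndarray) -> float:
        Q = build_Q(log_rates)
        P = _branch_P(ta, Q)
        ll, _, _ = _pruning(ta, P, tipL, prior)
        return 1e10 if ll == NEG_INF else -ll

    scale = _rate_scale(ta)
    lo, hi = math.log(1e-4 * scale), math.log(1e2 * scale)
    bounds = [(lo - 14.0, hi + 3.0)] * n_par  # generous box; floor ~ rate -> 0
    rng = np.random.default_rng(seed)
    starts = [np.full(n_par, math.log(scale))]
    starts += [rng.uniform(lo, hi, size=n_par) for _ in range(max(0, restarts - 1))]

    best = None
    n_ok = 0
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-10}
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun - 0.0:
                best = res
    if best is None:
        raise RuntimeError(
            f"Mk optimization failed in all {len(starts)} restarts ({family})"
        )
    Q = build_Q(best.x)
    model = MkModel(states, Q, prior)
    return MkFit(
        model=model,
        log_likelihood=-float(best.fun),
        family=family,
        rates=np.exp(best.x),
        n_restarts=len(starts),
        converged=bool(best.success) and n_ok > 0,
        diagnostics={"n_converged": n_ok, "optimizer": "L-BFGS-B"},
    )


def lrt_er_vs_ard(
    tree: Phylogeny | TreeArrays,
    tip_states: Mapping[str, object],
    restarts: int = 10,
    seed: int | None = 0,
) -> dict:
    """Likelihood-ratio test of ARD against the nested ER model.

    Degrees of freedom = (#ARD rates) - 1.  Returns both fits, the
    statistic and its chi-square p-value.
    """
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    fit_er = fit_mk(ta, tip_states, "ER", restarts=restarts, seed=seed)
    fit_ard = fit_mk(
        ta, tip_states, "ARD", restarts=restarts, seed=None if seed is None else seed + 1,
        states=fit_er.model.states,
    )
    k = fit_er.model.k
    df = k * (k - 1) - 1
    stat = 2.0 * (fit_ard.log_likelihood - fit_er.log_likelihood)
    stat = max(stat, 0.0)
    return {
        "er": fit_er,
        "ard": fit_ard,
        "statistic": stat,
        "df": df,
        "p_value": float(stats.chi2.sf(stat, df)),
    }


def er_profile_ci(
    tree: Phylogeny | TreeArrays,
    tip_states: Mapping[str, object],
    fit: MkFit,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the single ER rate."""
    if fit.family != "ER":
        raise ValueError("profile CI implemented for ER fits")
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    tipL = _tip_partials(ta, tip_states, fit.model.states)
    prior = fit.model.root_prior
    k = fit.model.k

    def ll(q: float) -> float:
        P = _branch_P(ta, er_generator(k, q))
        val, _, _ = _pruning(ta, P, tipL, prior)
        return val

    qhat = float(fit.rates[0])
    cut = fit.log_likelihood - 0.5 * stats.chi2.ppf(level, 1)

    def bound(lo: float, hi: float) -> float:
        for _ in range(80):
            mid = math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
            if ll(mid) < cut:
                lo_new, hi_new = (mid, hi) if mid < qhat else (lo, mid)
            else:
                lo_new, hi_new = (lo, mid) if mid < qhat else (mid, hi)
            lo, hi = lo_new, hi_new
            if hi - lo < 1e-9 * max(1.0, qhat):
                break
        return 0.5 * (lo + hi)

    lo = bound(qhat * 1e-6, qhat) if ll(qhat * 1e-6) < cut else 0.0
    hi_probe = qhat * 1e4 + 1e-8
    hi = bound(qhat, hi_probe) if ll(hi_probe) < cut else math.inf
    return lo, hi


# ----------------------------------------------------------------------
# ancestral marginals
# ----------------------------------------------------------------------

def ancestral_marginals(
    tree: Phylogeny | TreeArrays,
    tip_states: Mapping[str, object],
    fit: MkFit | MkModel,
) -> dict[int, np.ndarray]:
    """Marginal state probabilities at every internal node.

    Standard inside/outside computation: the marginal at a node is the
    normalized product of its subtree conditional likelihood and the
    "outside" likelihood of the rest of the tree (prior applied at the
    root), equivalent to the re-rooting procedure.
    """
    model = fit.model if isinstance(fit, MkFit) else fit
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    P = _branch_P(ta, model.Q)
    tipL = _tip_partials(ta, tip_states, model.states)
    ll, L, _ = _pruning(ta, P, tipL, model.root_prior)
    if ll == NEG_INF:
        raise ValueError("data have zero likelihood under the model")
    n, k = ta.n_nodes, model.k
    G = np.zeros((n, k))  # outside partials
    G[ta.root_index] = model.root_prior
    # preorder = reversed postorder
    for i in range(n - 1, -1, -1):
        kids = ta.children_index[i]
        if not kids:
            continue
        msgs = [P[c] @ L[c] for c in kids]
        for j, c in enumerate(kids):
            other = G[i].copy()
            for jj, m in enumerate(msgs):
                if jj != j:
                    other = other * m
            G[c] = other @ P[c]
            m = G[c].max()
            if m > 0:
                G[c] /= m
    out: dict[int, np.ndarray] = {}
    for i, nid in enumerate(ta.order):
        if ta.children_index[i]:
            v = G[i] * L[i]
            out[nid] = v / v.sum()
    return out


# ----------------------------------------------------------------------
# stochastic character mapping
# ----------------------------------------------------------------------

class _Uniformizer:
    """Cached uniformization operator R = I + Q/mu with lazy powers."""

    def __init__(self, Q: np.ndarray):
        self.k = Q.shape[0]
        self.mu = float(max(-Q.diagonal().min(), 1e-300))
        self.R = np.eye(self.k) + Q / self.mu
        self._powers = [np.eye(self.k), self.R.copy()]

    def power(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]


def _inv_cdf_choice(weights: np.ndarray, u: float) -> int:
    c = np.cumsum(weights)
    return int(np.searchsorted(c, u * c[-1], side="right").clip(0, weights.size - 1))


def _sample_path_uniformized(
    uni: _Uniformizer,
    P_t: np.ndarray,
    t: float,
    a: int,
    b: int,
    rng: np.random.Generator,
    max_jumps: int = 200,
) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on one branch by uniformization.

    Returns merged (state, duration) segments from the parent end (state
    ``a``) to the child end (state ``b``).
    """
    if t <= 0.0:
        return [(b, 0.0)]
    mu, R = uni.mu, uni.R
    p_ab = max(P_t[a, b], 1e-300)
    # sample the number of (possibly virtual) jumps
    u = rng.random()
    log_pois = -mu * t
    cum = 0.0
    n_jumps = None
    for n in range(max_jumps + 1):
        w = math.exp(log_pois) * uni.power(n)[a, b] / p_ab
        cum += w
        if u <= cum:
            n_jumps = n
            break
        log_pois += math.log(mu * t) - math.log(n + 1)
    if n_jumps is None:
        n_jumps = max_jumps  # truncation guard; astronomically rare
    if n_jumps == 0:
        return [(a, t)]
    # jump times: order statistics of uniforms
    times = np.sort(rng.uniform(0.0, t, size=n_jumps))
    # bridge over the jump chain
    seq = [a]
    for i in range(1, n_jumps):
        prev = seq[-1]
        rem = n_jumps - i  # jumps remaining after this one
        w = R[prev, :] * uni.power(rem)[:, b]
        if w.sum() <= 0:
            w = R[prev, :].copy()
        seq.append(_inv_cdf_choice(w, rng.random()))
    seq.append(b)
    # build segments, merging virtual (self) jumps
    segs: list[tuple[int, float]] = []
    cur_state = a
    cur_start = 0.0
    for i, s in enumerate(seq[1:]):
        jt = times[i]
        if s != cur_state:
            segs.append((cur_state, jt - cur_start))
            cur_state = s
            cur_start = jt
    segs.append((cur_state, t - cur_start))
    return segs


def sample_stochastic_maps(
    tree: Phylogeny | TreeArrays,
    tip_states: Mapping[str, object],
    fit: MkFit | MkModel,
    n_maps: int,
    seed: int | None = 0,
) -> list[StateMap]:
    """Sample full character histories conditional on the tip states.

    Node states are drawn from their joint conditional distribution
    (root from the prior-weighted root conditionals, then each child
    given its parent), and each branch path is sampled conditional on
    its endpoint states by uniformization.  Reproducible under ``seed``.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    model = fit.model if isinstance(fit, MkFit) else fit
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    Q = model.Q
    P = _branch_P(ta, Q)
    tipL = _tip_partials(ta, tip_states, model.states)
    ll, L, _ = _pruning(ta, P, tipL, model.root_prior)
    if ll == NEG_INF:
        raise ValueError("data have zero likelihood under the model")
    rng = np.random.default_rng(seed)
    n, k = ta.n_nodes, model.k
    root = ta.root_index
    root_post = model.root_prior * L[root]
    root_post = root_post / root_post.sum()
    uni = _Uniformizer(Q)
    bls = ta.branch_lengths
    nonroot = list(ta.nonroot())
    maps: list[StateMap] = []
    for _ in range(n_maps):
        node_state = np.empty(n, dtype=int)
        us = rng.random(n)
        node_state[root] = _inv_cdf_choice(root_post, us[root])
        for i in range(n - 2, -1, -1):  # preorder below root
            p = ta.parent_index[i]
            node_state[i] = _inv_cdf_choice(P[i][node_state[p], :] * L[i], us[i])
        segments: dict[int, list[tuple[int, float]]] = {}
        for i in nonroot:
            a = int(node_state[ta.parent_index[i]])
            b = int(node_state[i])
            segs = _sample_path_uniformized(uni, P[i], float(bls[i]), a, b, rng)
            segments[ta.order[i]] = segs
        maps.append(
            StateMap(
                states=model.states,
                segments=segments,
                node_states={ta.order[i]: int(node_state[i]) for i in range(n)},
            )
        )
    return maps


def count_transitions(state_map: StateMap) -> tuple[int, np.ndarray]:
    """Total and directed transition counts of one mapped history."""
    k = len(state_map.states)
    mat = np.zeros((k, k), dtype=int)
    for segs in state_map.segments.values():
        for (s1, _), (s2, _) in zip(segs, segs[1:]):
            mat[s1, s2] += 1
    return int(mat.sum()), mat


def minimum_transitions(ensemble: Sequence[StateMap]) -> dict:
    """Parsimony summary of a stochastic-map ensemble.

    The smallest per-map total transition count is taken as the most
    parsimonious history; the directed counts of that argmin map are
    reported alongside.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    totals = []
    mats = []
    for m in ensemble:
        tot, mat = count_transitions(m)
        totals.append(tot)
        mats.append(mat)
    i = int(np.argmin(totals))
    return {
        "minimum": int(totals[i]),
        "argmin_index": i,
        "directed_counts": mats[i],
        "per_map_totals": np.asarray(totals),
        "mean": float(np.mean(totals)),
    }
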