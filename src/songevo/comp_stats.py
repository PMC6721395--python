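"""Simulation-based phylogenetic ANOVA, Holm correction, lambda-PGLS,
and a sister-pair (cherry) rate scan.

The phylogenetic ANOVA follows the simulation approach of Garland et
al.: the observed one-way F statistic is referred to a null distribution
of F values computed on Brownian-motion datasets simulated on the tree
with the single-rate ML variance fitted from the data.  P-values use the
add-one estimator ``(1 + #{F_sim >= F_obs}) / (n_sim + 1)`` so a
simulation p is never exactly zero.

PGLS uses Pagel's lambda residual correlation: off-diagonal elements of
the phylogenetic correlation matrix are multiplied by lambda, which is
profiled by maximum likelihood over ``[0, lambda_max]`` where
``lambda_max`` is the largest value keeping the matrix positive
definite (this can exceed 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .phylo_core import Phylogeny, TreeArrays, linearize, phylo_covariance
from .rate_models import fit_bm

__all__ = [
    "PhylAnovaResult",
    "PglsFit",
    "HolmResult",
    "anova_f",
    "phyl_anova",
    "holm",
    "fit_pgls",
    "sister_pair_rate_scan",
]


@dataclass
class PhylAnovaResult:
    f_observed: float
    p_value: float
    group_means: dict
    group_sizes: dict
    posthoc_t: dict  # (g1, g2) -> T statistic
    posthoc_p: dict  # (g1, g2) -> Holm-adjusted simulation p
    n_sim: int
    seed: int | None


@dataclass
class PglsFit:
    slope: float
    std_error: float
    lam: float
    lam_max: float
    t_value: float
    p_value: float
    intercept: float
    log_likelihood: float
    lam_at_boundary: bool
    n: int


@dataclass
class HolmResult:
    p_values: np.ndarray
    thresholds: np.ndarray  # aligned to the original test order
    reject: np.ndarray
    order: np.ndarray  # ascending-p permutation
    alpha: float
    adjusted_p: np.ndarray = field(default=None)


# ----------------------------------------------------------------------
# ANOVA
# ----------------------------------------------------------------------

def anova_f(values: np.ndarray, groups: Sequence) -> float:
    """Classical one-way F = MS_between / MS_within."""
    x = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    if labs.size < 2:
        raise ValueError("need at least 2 groups")
    n = x.size
    if n - labs.size < 1:
        raise ValueError("no residual degrees of freedom")
    grand = x.mean()
    ssb = ssw = 0.0
    for g in labs:
        xi = x[groups == g]
        ssb += xi.size * (xi.mean() - grand) ** 2
        ssw += ((xi - xi.mean()) ** 2).sum()
    msb = ssb / (labs.size - 1)
    msw = ssw / (n - labs.size)
    if msw == 0.0:
        return float("inf")
    return float(msb / msw)


def _f_many(X: np.ndarray, groups: np.ndarray, labs: np.ndarray) -> np.ndarray:
    """Vectorized one-way F over the columns of X (n x n_sim)."""
    n, _ = X.shape
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in labs:
        Xi = X[groups == g]
        mi = Xi.mean(axis=0)
        ssb += Xi.shape[0] * (mi - grand) ** 2
        ssw += ((Xi - mi) ** 2).sum(axis=0)
    msb = ssb / (labs.size - 1)
    msw = ssw / (n - labs.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        return msb / msw


def _welch_t(x1: np.ndarray, x2: np.ndarray) -> float:
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    se = np.sqrt(v1 / x1.size + v2 / x2.size)
    if se == 0:
        return float("inf")
    return float((x1.mean() - x2.mean()) / se)


def _welch_t_many(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        v1 = X1.var(axis=0, ddof=1) if X1.shape[0] > 1 else np.full(X1.shape[1], np.nan)
        v2 = X2.var(axis=0, ddof=1) if X2.shape[0] > 1 else np.full(X2.shape[1], np.nan)
        se = np.sqrt(v1 / X1.shape[0] + v2 / X2.shape[0])
        return (X1.mean(axis=0) - X2.mean(axis=0)) / se


def phyl_anova(
    tree: Phylogeny | TreeArrays,
    values: Mapping[str, float],
    groups: Mapping[str, object],
    n_sim: int = 1000,
    seed: int | None = 0,
    posthoc: bool = True,
) -> PhylAnovaResult:
    """Simulation-based phylogenetic ANOVA with post-hoc pairwise tests.

    Null datasets are Brownian simulations on the tree at the ML
    single-rate variance of the observed data; the simulation p-value is
    add-one.  Post-hoc pairwise Welch T statistics are referred to the
    same simulated null and Holm-adjusted within the pairwise family.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    labels = [
        l
        for l in ta.tip_labels
        if values.get(l) is not None and groups.get(l) is not None
    ]
    x = np.array([float(values[l]) for l in labels])
    g = np.array([groups[l] for l in labels], dtype=object)
    labs = np.unique(g)
    missing = [lab for lab in labs if (g == lab).sum() == 0]
    if labs.size < 2:
        raise ValueError("need at least 2 groups present among tree tips")
    if missing:
        raise ValueError(f"groups with no tree-matched rows: {missing}")

    C, _ = _covariance_for(ta, labels)
    f_obs = anova_f(x, g)
    base = fit_bm(C, x)
    rng = np.random.default_rng(seed)
    Lc = np.linalg.cholesky(float(base.sigma2[0]) * C)
    Z = rng.standard_normal((len(labels), n_sim))
    X = Lc @ Z  # group structure is null: common mean cancels in F
    f_sim = _f_many(X, g, labs)
    p = (1.0 + float(np.sum(f_sim >= f_obs))) / (n_sim + 1.0)

    means = {lab: float(x[g == lab].mean()) for lab in labs}
    sizes = {lab: int((g == lab).sum()) for lab in labs}

    posthoc_t: dict = {}
    posthoc_p: dict = {}
    if posthoc and labs.size >= 2:
        pairs = [
            (labs[i], labs[j])
            for i in range(labs.size)
            for j in range(i + 1, labs.size)
        ]
        raw = []
        for g1, g2 in pairs:
            t_obs = _welch_t(x[g == g1], x[g == g2])
            t_sim = _welch_t_many(X[g == g1], X[g == g2])
            pp = (1.0 + float(np.sum(np.abs(t_sim) >= abs(t_obs)))) / (n_sim + 1.0)
            posthoc_t[(g1, g2)] = abs(t_obs)
            raw.append(pp)
        adj = holm(np.array(raw)).adjusted_p
        for (g1, g2), pa in zip(pairs, adj):
            posthoc_p[(g1, g2)] = float(pa)
    return PhylAnovaResult(
        f_observed=f_obs,
        p_value=float(p),
        group_means=means,
        group_sizes=sizes,
        posthoc_t=posthoc_t,
        posthoc_p=posthoc_p,
        n_sim=n_sim,
        seed=seed,
    )


def _covariance_for(ta: TreeArrays, labels: Sequence[str]):
    cov_full, order = phylo_covariance(ta.tree)
    idx = {lab: i for i, lab in enumerate(order)}
    sel = np.array([idx[l] for l in labels])
    return cov_full[np.ix_(sel, sel)], list(labels)


# ----------------------------------------------------------------------
# Holm-Bonferroni
# ----------------------------------------------------------------------

def holm(p_values: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm-Bonferroni sequential correction.

    Sorted ascending, the i-th smallest p (1-based) is compared against
    ``alpha / (m - i + 1)``; rejection stops at the first failure.  Ties
    keep their original order (stable sort).  Also returns step-down
    adjusted p-values (monotone cummax of ``(m - i + 1) * p``).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thr_sorted = alpha / (m - np.arange(m))
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] <= thr_sorted[i]:
            reject_sorted[i] = True
        else:
            break
    adj_sorted = np.maximum.accumulate(np.minimum(1.0, (m - np.arange(m)) * p[order]))
    thresholds = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    adjusted = np.empty(m)
    thresholds[order] = thr_sorted
    reject[order] = reject_sorted
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return HolmResult(
        p_values=p,
        thresholds=thresholds,
        reject=reject,
        order=order,
        alpha=alpha,
        adjusted_p=adjusted,
    )


# ----------------------------------------------------------------------
# PGLS with Pagel's lambda
# ----------------------------------------------------------------------

def fit_pgls(
    tree: Phylogeny | TreeArrays,
    response: Mapping[str, float],
    predictor: Mapping[str, float],
    n_grid: int = 64,
    lam: float | None = None,
) -> PglsFit:
    """Phylogenetic GLS with ML Pagel's lambda.

    The residual correlation is the phylogenetic correlation matrix with
    off-diagonals multiplied by lambda.  Lambda is profiled on a grid
    over ``[0, lambda_max]`` refined by golden-section search;
    ``lambda_max = 1 / (1 - e_min)`` with ``e_min`` the smallest
    eigenvalue of the correlation matrix, the positive-definiteness
    bound (not clamped to 1).  Passing ``lam`` fixes lambda instead of
    profiling it (``lam=0`` reduces to OLS, ``lam=1`` to plain
    phylogenetic GLS).  The slope p-value is two-sided from a t
    distribution with n - 2 df.
    """
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    labels = [
        l
        for l in ta.tip_labels
        if response.get(l) is not None and predictor.get(l) is not None
    ]
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 complete rows")
    y = np.array([float(response[l]) for l in labels])
    xv = np.array([float(predictor[l]) for l in labels])
    C, _ = _covariance_for(ta, labels)
    d = np.sqrt(np.diag(C))
    R0 = C / np.outer(d, d)
    emin = float(np.linalg.eigvalsh(R0).min())
    lam_max = 1.0 / (1.0 - emin) - 1e-9 if emin < 1.0 else 10.0

    X = np.column_stack([np.ones(n), xv])

    def profile(lam: float):
        R = lam * R0 + (1.0 - lam) * np.eye(n)
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            return -1e12, None
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        s2 = float(resid @ resid) / n  # ML sigma2
        if s2 <= 0:
            return -1e12, None
        logdet = 2.0 * np.log(np.diag(L)).sum()
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        return ll, (beta, L, Xw, resid, s2)

    if lam is None:
        grid = np.linspace(0.0, lam_max, n_grid)
        lls = np.array([profile(l)[0] for l in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        # golden-section refinement
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c1 = b - gr * (b - a)
        c2 = a + gr * (b - a)
        f1, f2 = profile(c1)[0], profile(c2)[0]
        for _ in range(60):
            if b - a < 1e-10:
                break
            if f1 < f2:
                a, c1, f1 = c1, c2, f2
                c2 = a + gr * (b - a)
                f2 = profile(c2)[0]
            else:
                b, c2, f2 = c2, c1, f1
                c1 = b - gr * (b - a)
                f1 = profile(c1)[0]
        lam = float(0.5 * (a + b))
    ll, parts = profile(lam)
    beta, L, Xw, resid, s2_ml = parts
    s2_hat = float(resid @ resid) / (n - 2)  # unbiased, for standard errors
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = float(np.sqrt(s2_hat * XtX_inv[1, 1]))
    t = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    boundary = lam < 1e-8 or lam > lam_max - 1e-6
    return PglsFit(
        slope=float(beta[1]),
        std_error=se,
        lam=lam,
        lam_max=float(lam_max),
        t_value=t,
        p_value=p,
        intercept=float(beta[0]),
        log_likelihood=float(ll),
        lam_at_boundary=bool(boundary),
        n=n,
    )


# ----------------------------------------------------------------------
# sister-pair rate scan
# ----------------------------------------------------------------------

def sister_pair_rate_scan(
    tree: Phylogeny | TreeArrays,
    values: Mapping[str, float],
    n_perm: int = 1000,
    seed: int | None = 0,
) -> dict:
    """Rate-vs-size scan across cherries (monophyletic species pairs).

    For each cherry the local rate proxy is the squared standardized
    contrast ``(x1 - x2)^2 / (t1 + t2)`` and the size proxy the pair
    mean; association is the Spearman correlation across pairs with a
    permutation p-value.  Degenerate input (all proxies zero) is
    flagged, not raised.
    """
    ta = tree if isinstance(tree, TreeArrays) else linearize(tree)
    t = ta.tree
    pairs = []
    for node in t.postorder():
        kids = t.children[node]
        if len(kids) == 2 and all(t.is_tip(c) for c in kids):
            l1, l2 = t.labels[kids[0]], t.labels[kids[1]]
            if values.get(l1) is None or values.get(l2) is None:
                continue
            x1, x2 = float(values[l1]), float(values[l2])
            tt = t.branch_length[kids[0]] + t.branch_length[kids[1]]
            if tt <= 0:
                continue
            pairs.append(
                {
                    "pair": (l1, l2),
                    "rate_proxy": (x1 - x2) ** 2 / tt,
                    "mean": 0.5 * (x1 + x2),
                }
            )
    if len(pairs) < 3:
        raise ValueError("need at least 3 cherries with data")
    r = np.array([p["rate_proxy"] for p in pairs])
    m = np.array([p["mean"] for p in pairs])
    if np.allclose(r, 0.0):
        return {"pairs": pairs, "rho": np.nan, "p_value": np.nan, "degenerate": True}
    rho = float(stats.spearmanr(m, r).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rho_p = stats.spearmanr(m, rng.permutation(r)).statistic
        if abs(rho_p) >= abs(rho):
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return {"pairs": pairs, "rho": rho, "p_value": float(p), "degenerate": False}
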