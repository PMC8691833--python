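"""Phylogenetic comparative statistics for melanosome traits.

Continuous traits measured on species are not independent samples: close
relatives resemble each other.  Under a Brownian-motion (BM) model of trait
evolution the expected covariance of two tips is the evolutionary rate times
the length of their shared root path, which turns a phylogeny into a
covariance matrix.  This module builds on that:

* BM simulation on a tree (the engine behind all the null distributions);
* simulation-based phylogenetic ANOVA and pairwise t-tests, where the observed
  F (or t) statistic is referred to a null distribution generated by BM
  simulation with the maximum-likelihood rate;
* Pagel's lambda, the ML multiplier on the off-diagonal covariance that
  measures phylogenetic signal;
* an excess-mass multimodality test calibrated by a smoothed bootstrap at the
  critical bandwidth;
* ordinary least squares for the melanosome-modification effect models on
  simulation output, and a Gaussian mixed model with phylogenetic and patch
  random effects (REML) for plumage data.

Fits return small statsmodels-style results objects with a ``summary()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize, minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_tree",
    "tree_vcv",
    "simulate_bm",
    "phylo_anova",
    "PhyloAnovaResult",
    "phylo_pairwise_t",
    "pagels_lambda",
    "PagelsLambdaResult",
    "mode_test",
    "excess_mass_stat",
    "critical_bandwidth",
    "fit_sim_effects",
    "SimEffectsResult",
    "fit_plumage_lmm",
    "PlumageLMMResult",
    "average_duplicates",
]


# ---------------------------------------------------------------------------
# trees

def load_tree(source: str) -> dendropy.Tree:
    """Load a rooted Newick tree from a path or a Newick string."""
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance matrix: shared root-path length per tip pair.

    Branch lengths missing on the tree are treated as zero.  Returns the tip
    labels (taxon order of the tree) and the dense matrix.
    """
    tree = tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
        edge = node.edge.length or 0.0
        node._depth = parent_depth + edge

    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(taxa)) != len(taxa):
        raise ValueError("tip labels must be unique")
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tips = [index[node.taxon.label]]
            C[node._tips[0], node._tips[0]] = node._depth
        else:
            children = node.child_nodes()
            tips: list[int] = []
            for a_i, child_a in enumerate(children):
                for child_b in children[a_i + 1 :]:
                    for i in child_a._tips:
                        for j in child_b._tips:
                            C[i, j] = C[j, i] = node._depth
                tips.extend(child_a._tips)
            node._tips = tips
    if np.all(np.diag(C) <= 0):
        raise ValueError("degenerate tree: zero total depth")
    return taxa, C


def _chol_like(C: np.ndarray) -> np.ndarray:
    """Cholesky factor with an eigenvalue fallback for singular matrices."""
    try:
        return np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def simulate_bm(
    tree: dendropy.Tree,
    rate: float = 1.0,
    seed: int | None = None,
    n_traits: int = 1,
    root_state: float = 0.0,
) -> pd.DataFrame:
    """Brownian-motion tip values: multivariate normal with covariance rate*C."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    taxa, C = tree_vcv(tree)
    L = _chol_like(C)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((len(taxa), n_traits))
    X = root_state + np.sqrt(rate) * (L @ Z)
    return pd.DataFrame(X, index=taxa, columns=[f"trait_{k}" for k in range(n_traits)])


# ---------------------------------------------------------------------------
# helpers shared by the simulation-based tests

def _align(trait: pd.Series, groups: pd.Series, taxa: list[str]):
    trait = trait.reindex(taxa)
    groups = groups.reindex(taxa)
    if trait.isna().any() or groups.isna().any():
        missing = sorted(set(taxa) - set(trait.dropna().index))
        raise ValueError(f"trait/groups missing for tips: {missing[:5]}...")
    return trait.to_numpy(dtype=float), groups.to_numpy()


def _ml_bm_rate(x: np.ndarray, C: np.ndarray) -> float:
    """ML Brownian rate given the tree covariance (GLS mean profiled out)."""
    n = len(x)
    Cinv = np.linalg.pinv(C + 1e-12 * np.eye(n))
    one = np.ones(n)
    mu = (one @ Cinv @ x) / (one @ Cinv @ one)
    resid = x - mu
    return float(resid @ Cinv @ resid / n)


def _f_stats(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each column of X (tips x replicates)."""
    X = np.atleast_2d(X.T).T
    n, m = X.shape
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    G = np.zeros((k, n))
    G[inverse, np.arange(n)] = 1.0
    sizes = G.sum(axis=1)[:, None]
    group_means = (G @ X) / sizes
    grand = X.mean(axis=0, keepdims=True)
    ss_between = (sizes * (group_means - grand) ** 2).sum(axis=0)
    resid = X - group_means[inverse]
    ss_within = (resid**2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    return (ss_between / df_b) / (ss_within / df_w)


@dataclass
class PhyloAnovaResult:
    F_obs: float
    p_sim: float
    n_sim: int
    df_between: int
    df_within: int
    rate: float

    def summary(self) -> str:
        return (
            "Simulation-based phylogenetic ANOVA\n"
            f"  F({self.df_between}, {self.df_within}) = {self.F_obs:.4g}\n"
            f"  p (BM simulation, {self.n_sim} draws) = {self.p_sim:.4g}\n"
            f"  ML Brownian rate = {self.rate:.4g}"
        )


def _check_groups(groups: np.ndarray) -> None:
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise ValueError(f"singleton groups not allowed: {list(small)}")


def phylo_anova(
    tree: dendropy.Tree,
    trait: pd.Series,
    groups: pd.Series,
    n_sim: int = 1000,
    seed: int | None = None,
) -> PhyloAnovaResult:
    """Simulation-based phylogenetic one-way ANOVA.

    The observed F comes from an ordinary one-way ANOVA; its null distribution
    comes from ``n_sim`` BM simulations on the tree with the ML rate fitted to
    the observed trait.  The p-value uses the add-one continuity correction
    p = (1 + #{F_sim >= F_obs}) / (n_sim + 1).
    """
    taxa, C = tree_vcv(tree)
    x, g = _align(trait, groups, taxa)
    _check_groups(g)
    F_obs = float(_f_stats(x[:, None], g)[0])
    rate = _ml_bm_rate(x, C)
    rng = np.random.default_rng(seed)
    L = _chol_like(C)
    sims = np.sqrt(rate) * (L @ rng.standard_normal((len(taxa), n_sim)))
    F_sim = _f_stats(sims, g)
    p = (1.0 + np.sum(F_sim >= F_obs)) / (n_sim + 1.0)
    labels = np.unique(g)
    return PhyloAnovaResult(
        F_obs, float(p), n_sim, len(labels) - 1, len(x) - len(labels), rate
    )


def _t_stats(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pooled two-sample t for each column of X restricted to two groups."""
    Xa, Xb = X[mask_a], X[mask_b]
    na, nb = Xa.shape[0], Xb.shape[0]
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    va = Xa.var(axis=0, ddof=1)
    vb = Xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def phylo_pairwise_t(
    tree: dendropy.Tree,
    trait: pd.Series,
    groups: pd.Series,
    n_sim: int = 1000,
    seed: int | None = None,
    correction: str = "holm",
) -> pd.DataFrame:
    """Phylogenetic pairwise t-tests with simulation-based null distributions.

    Each pair of groups is compared with a pooled two-sample t statistic; the
    null t values come from the same BM simulations used by the ANOVA.
    Two-sided p-values are corrected for multiplicity (Holm by default) and
    returned as a symmetric matrix with NaN on the diagonal.
    """
    taxa, C = tree_vcv(tree)
    x, g = _align(trait, groups, taxa)
    _check_groups(g)
    labels = list(np.unique(g))
    rate = _ml_bm_rate(x, C)
    rng = np.random.default_rng(seed)
    L = _chol_like(C)
    sims = np.sqrt(rate) * (L @ rng.standard_normal((len(taxa), n_sim)))
    raw, pairs = [], []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            mask_a, mask_b = g == la, g == lb
            t_obs = float(_t_stats(x[:, None], mask_a, mask_b)[0])
            t_sim = _t_stats(sims, mask_a, mask_b)
            p = (1.0 + np.sum(np.abs(t_sim) >= abs(t_obs))) / (n_sim + 1.0)
            raw.append(p)
            pairs.append((la, lb))
    if correction is not None and correction != "none":
        adj = multipletests(raw, method=correction)[1]
    else:
        adj = np.asarray(raw)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (la, lb), p in zip(pairs, adj):
        out.loc[la, lb] = out.loc[lb, la] = p
    return out


# ---------------------------------------------------------------------------
# Pagel's lambda

@dataclass
class PagelsLambdaResult:
    lambda_hat: float
    logL: float
    logL0: float
    p_vs_zero: float
    identifiable: bool = True

    def summary(self) -> str:
        note = "" if self.identifiable else "  (star tree: lambda unidentifiable)\n"
        return (
            "Pagel's lambda (ML)\n"
            f"  lambda_hat = {self.lambda_hat:.4f}\n"
            f"  logL = {self.logL:.4f}; logL(lambda=0) = {self.logL0:.4f}\n"
            f"  LRT p (lambda > 0) = {self.p_vs_zero:.4g}\n" + note
        )


def _lambda_loglik(lam: float, x: np.ndarray, C: np.ndarray) -> float:
    n = len(x)
    Cl = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    try:
        L = np.linalg.cholesky(Cl + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    one = np.ones(n)
    w1 = solve_triangular(L, one, lower=True)
    wx = solve_triangular(L, x, lower=True)
    mu = (w1 @ wx) / (w1 @ w1)
    resid = wx - mu * w1
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def pagels_lambda(tree: dendropy.Tree, trait: pd.Series) -> PagelsLambdaResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test against 0.

    Lambda multiplies the off-diagonal entries of the BM covariance matrix:
    0 means no phylogenetic signal, 1 means pure Brownian motion.  On a star
    tree the off-diagonals vanish and lambda is unidentifiable; the result is
    returned flagged rather than raising.
    """
    taxa, C = tree_vcv(tree)
    x = trait.reindex(taxa).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("trait missing for some tips")
    if len(x) < 4:
        raise ValueError("at least 4 tips required")
    if np.allclose(x, x[0]):
        raise ValueError("trait is constant; lambda undefined")
    off = C - np.diag(np.diag(C))
    if np.max(np.abs(off)) < 1e-12 * np.max(np.diag(C)):
        ll0 = _lambda_loglik(0.0, x, C)
        return PagelsLambdaResult(np.nan, ll0, ll0, 1.0, identifiable=False)
    res = minimize_scalar(
        lambda lam: -_lambda_loglik(lam, x, C),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(float(res.x), -res.fun)]
    for lam in (0.0, 1.0):
        candidates.append((lam, _lambda_loglik(lam, x, C)))
    lam_hat, ll = max(candidates, key=lambda t: t[1])
    ll0 = _lambda_loglik(0.0, x, C)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return PagelsLambdaResult(lam_hat, ll, ll0, p)


# ---------------------------------------------------------------------------
# excess-mass multimodality test

def _excess_mass_curves(x_sorted: np.ndarray, lambdas: np.ndarray, k_max: int) -> np.ndarray:
    """E_k(lambda) for k = 1..k_max; shape (k_max, n_lambdas).

    E_k(lambda) is the maximum over k disjoint intervals [x_i, x_j] of the
    empirical mass minus lambda times the interval lengths.  Computed by the
    prefix-maximum recurrence, vectorised over the lambda grid.
    """
    n = x_sorted.shape[0]
    lam = lambdas[:, None]  # (L, 1)
    xi = x_sorted[None, :]  # (1, n)
    idx = np.arange(n)[None, :]
    # score of interval [i, j] = (j - i + 1)/n - lam (x_j - x_i)
    #                          = (j+1)/n - lam x_j + (lam x_i - i/n)
    g = lam * xi - idx / n  # (L, n)
    tail = (idx + 1) / n - lam * xi  # (L, n)
    E = np.empty((k_max, lambdas.shape[0]))
    prev_best_upto = None  # M_{k-1}(i-1): best k-1 intervals strictly left of i
    for k in range(1, k_max + 1):
        if k == 1:
            h = g
        else:
            h = g + prev_best_upto
        best_end = tail + np.maximum.accumulate(h, axis=1)  # best k intervals ending at j
        running = np.maximum.accumulate(best_end, axis=1)  # best k intervals within [0, j]
        E[k - 1] = running[:, -1]
        # shift: best k intervals strictly left of position i (i.e. within [0, i-1])
        prev_best_upto = np.concatenate(
            [np.zeros((lambdas.shape[0], 1)), running[:, :-1]], axis=1
        )
    return np.maximum(E, 0.0)


def _lambda_grid(x: np.ndarray, n_grid: int = 64) -> np.ndarray:
    scale = min(np.std(x, ddof=1), stats.iqr(x) / 1.349) or np.std(x, ddof=1)
    if scale <= 0:
        scale = max(np.ptp(x), 1.0)
    return np.geomspace(1e-3 / scale, 5.0 / scale, n_grid)


def excess_mass_stat(x: np.ndarray, null_modes: int = 1, n_grid: int = 64) -> float:
    """Excess-mass statistic D = max_lambda [E_{m+1}(lambda) - E_m(lambda)]."""
    xs = np.sort(np.asarray(x, dtype=float))
    lambdas = _lambda_grid(xs, n_grid)
    E = _excess_mass_curves(xs, lambdas, null_modes + 1)
    return float(np.max(E[null_modes] - E[null_modes - 1]))


def _kde_n_modes(x: np.ndarray, h: float, n_eval: int = 512) -> int:
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_eval)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    d = np.sign(np.diff(dens))
    d = d[d != 0]
    return int(np.sum((d[:-1] > 0) & (d[1:] < 0)))


def critical_bandwidth(
    x: np.ndarray, null_modes: int = 1, n_grid: int = 60
) -> float:
    """Smallest bandwidth (log grid) whose Gaussian KDE has <= null_modes modes."""
    x = np.asarray(x, dtype=float)
    s = np.std(x, ddof=1)
    hs = np.geomspace(0.01 * s, 5.0 * s, n_grid)
    lo, hi = 0, len(hs) - 1
    if _kde_n_modes(x, hs[hi]) > null_modes:
        return hs[hi]
    while lo < hi:  # first h with <= null_modes modes (mode count is ~monotone)
        mid = (lo + hi) // 2
        if _kde_n_modes(x, hs[mid]) <= null_modes:
            hi = mid
        else:
            lo = mid + 1
    return float(hs[lo])


def mode_test(
    x: np.ndarray,
    null_modes: int = 1,
    n_boot: int = 500,
    seed: int | None = None,
) -> float:
    """Excess-mass test of "at most ``null_modes`` modes".

    The observed excess mass is calibrated by a smoothed bootstrap: resamples
    are drawn from the Gaussian KDE at the critical bandwidth (the smallest
    bandwidth whose KDE is reduced to the null number of modes), with the
    variance inflation of the smoothing corrected, and the p-value is the
    add-one-corrected proportion of bootstrap statistics at least as large as
    the observed one.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("at least 20 observations required")
    D_obs = excess_mass_stat(x, null_modes)
    h = critical_bandwidth(x, null_modes)
    rng = np.random.default_rng(seed)
    n = x.size
    var = np.var(x, ddof=1)
    shrink = 1.0 / np.sqrt(1.0 + h**2 / var)
    mean = x.mean()
    count = 0
    for _ in range(n_boot):
        base = rng.choice(x, size=n, replace=True)
        y = mean + (base - mean + h * rng.standard_normal(n)) * shrink
        if excess_mass_stat(y, null_modes) >= D_obs:
            count += 1
    return (1.0 + count) / (n_boot + 1.0)


# ---------------------------------------------------------------------------
# effect models

MODIFICATION_COLUMNS = ("thin", "hollow", "platelet", "hollow_x_platelet")


@dataclass
class SimEffectsResult:
    tables: dict  # response -> DataFrame(coef, se, ci_low, ci_high, p)

    def summary(self) -> str:
        buf = io.StringIO()
        for resp, tab in self.tables.items():
            buf.write(f"OLS effects on {resp}\n")
            buf.write(tab.to_string(float_format=lambda v: f"{v: .4f}"))
            buf.write("\n\n")
        return buf.getvalue()


def fit_sim_effects(
    table: pd.DataFrame,
    responses: tuple[str, ...] = ("saturation", "log_double_cone", "log_peak_reflectance"),
    predictors: tuple[str, ...] = MODIFICATION_COLUMNS,
) -> SimEffectsResult:
    """OLS of color variables on binary melanosome-modification predictors.

    The design uses 0/1 columns for thin melanin layers, hollowness, platelet
    shape and the hollowness x platelet interaction; responses named log_*
    are expected already log-transformed by the caller.
    """
    import statsmodels.api as sm

    X = table.loc[:, list(predictors)].astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify offending columns by dropping one at a time
        bad = [
            col
            for col in X.columns
            if np.linalg.matrix_rank(Xc.drop(columns=[col]).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    tables = {}
    for resp in responses:
        fit = sm.OLS(table[resp].astype(float), Xc).fit()
        ci = fit.conf_int(alpha=0.05)
        tables[resp] = pd.DataFrame(
            {
                "coef": fit.params,
                "se": fit.bse,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": fit.pvalues,
            }
        )
    return SimEffectsResult(tables)


# ---------------------------------------------------------------------------
# phylogenetic mixed model

@dataclass
class PlumageLMMResult:
    params: pd.Series
    se: pd.Series
    conf_int: pd.DataFrame
    sigma2_resid: float
    sigma2_phylo: float
    sigma2_patch: float
    reml: float
    converged: bool

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "ci_low": self.conf_int["ci_low"],
                "ci_high": self.conf_int["ci_high"],
            }
        )
        return (
            "Phylogenetic mixed model (REML)\n"
            + tab.to_string(float_format=lambda v: f"{v: .4f}")
            + f"\n  var(residual) = {self.sigma2_resid:.4g}"
            + f"\n  var(phylogeny) = {self.sigma2_phylo:.4g}"
            + f"\n  var(patch) = {self.sigma2_patch:.4g}\n"
        )


def _reml_neg(theta, y, X, A, B):
    g1, g2 = np.exp(theta)
    n, p = X.shape
    V = np.eye(n) + g1 * A + g2 * B
    try:
        Lv = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    Vi_y = cho_solve((Lv, True), y)
    Vi_X = cho_solve((Lv, True), X)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError:
        return 1e10
    resid = y - X @ beta
    Vi_r = cho_solve((Lv, True), resid)
    quad = float(resid @ Vi_r)
    sigma2 = quad / (n - p)
    logdetV = 2.0 * np.sum(np.log(np.diag(Lv)))
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0 or sigma2 <= 0:
        return 1e10
    return 0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        + logdetV
        + logdetXtViX
        + (n - p)
    )


def fit_plumage_lmm(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    response: str,
    fixed: tuple[str, ...],
    species_col: str = "species",
    patch_col: str = "patch",
    var_components: tuple[float, float] | None = None,
) -> PlumageLMMResult:
    """Gaussian mixed model with phylogenetic and patch random effects.

    y = X beta + u_phylo + u_patch + e, where u_phylo has covariance
    sigma2_phylo * C (C the tree's shared-path matrix, mapped to observations
    through species) and u_patch is an i.i.d. random intercept per patch.
    Variance ratios are estimated by REML on a log scale; fixed effects are
    GLS at the optimum with Wald (normal) intervals.  ``var_components``
    fixes the two variance ratios (phylo/resid, patch/resid) instead of
    estimating them; (0, 0) reduces the fit to ordinary least squares.
    """
    taxa, C = tree_vcv(tree)
    missing = set(table[species_col]) - set(taxa)
    if missing:
        raise ValueError(f"species absent from the tree: {sorted(missing)[:5]}")
    C = C / np.diag(C).mean()  # unit-depth scaling, keeps variances comparable
    sp_index = {s: i for i, s in enumerate(taxa)}
    rows = table[species_col].map(sp_index).to_numpy()
    Zs = np.zeros((len(table), len(taxa)))
    Zs[np.arange(len(table)), rows] = 1.0
    A = Zs @ C @ Zs.T
    patches, p_inv = np.unique(table[patch_col].to_numpy(), return_inverse=True)
    Zp = np.zeros((len(table), len(patches)))
    Zp[np.arange(len(table)), p_inv] = 1.0
    B = Zp @ Zp.T

    y = table[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in fixed]
    )
    names = ["const"] + list(fixed)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")

    if var_components is not None:
        g1, g2 = (max(float(v), 0.0) for v in var_components)
        reml = -_reml_neg(np.log(np.array([g1, g2]) + 1e-300), y, X, A, B)
        converged = True
    else:
        best = None
        for start in ([-2.0, -2.0], [0.0, 0.0], [-6.0, -6.0]):
            res = minimize(
                _reml_neg, start, args=(y, X, A, B), method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        g1, g2 = np.exp(np.clip(best.x, -30, 30))
        reml = -float(best.fun)
        converged = bool(best.success)
    n, p = X.shape
    V = np.eye(n) + g1 * A + g2 * B
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ Vi @ resid) / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame(
        {"ci_low": beta - z * se, "ci_high": beta + z * se}, index=names
    )
    return PlumageLMMResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        conf_int=ci,
        sigma2_resid=sigma2,
        sigma2_phylo=sigma2 * g1,
        sigma2_patch=sigma2 * g2,
        reml=reml,
        converged=converged,
    )


def average_duplicates(
    table: pd.DataFrame, species_col: str = "species"
) -> pd.DataFrame:
    """Collapse multiple rows per species to their (numeric) mean.

    Non-numeric columns keep the first value of each species; this is applied
    before any comparative test so every species contributes once.
    """
    numeric = table.select_dtypes(include=[np.number]).columns
    other = [c for c in table.columns if c not in numeric and c != species_col]
    agg = {c: "mean" for c in numeric}
    agg.update({c: "first" for c in other})
    return table.groupby(species_col, sort=False).agg(agg).reset_index()
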