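"""Phylogenetic logistic regression for a binary trait (penalized ML).

The response (here: apparent = 1, nonapparent = 0) is modelled as a
two-state Markov process switching along the tree.  The stationary
probability of state 1 on the branch above tip *i* is
``mu_i = logistic(x_i' beta)``; internal branches take the mean of the
stationary probabilities of their descendant tips.  A single switching
rate ``alpha`` (per unit branch length) controls how fast tip values
decorrelate: large ``alpha`` makes tips independent draws from their
logistic means, small ``alpha`` makes close relatives nearly identical.
The likelihood of the tip data is computed exactly by pruning and a
Firth-type penalty ``0.5 log det(X' W X)`` (W = diag(mu(1-mu)))
stabilises the estimates under separation — maximum penalized
likelihood estimation (MPLE).

On a star tree the fit reduces to ordinary Firth-penalized logistic
regression, because without shared branches the switching process
contributes no correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .errors import ConvergenceError, DegenerateInputError, InvalidInputError
from .mkmap import TreeIndex, index_tree

__all__ = ["PhyloGLMFit", "fit_phyloglm", "predictor_correlation"]

#: alpha search box, in units of 1/tree-height (the usual "btol" box)
ALPHA_BOUNDS = (1e-7, 50.0)


@dataclass
class PhyloGLMFit:
    """Penalized-ML estimates of the phylogenetic logistic model."""

    coefficients: pd.Series
    std_errors: pd.Series
    z_scores: pd.Series
    p_values: pd.Series
    alpha: float  # switching rate (phylogenetic signal attenuation)
    loglik: float  # penalized log-likelihood at the optimum
    converged: bool
    n: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "se": self.std_errors,
            "z": self.z_scores,
            "p": self.p_values,
        })


class _Engine:
    """Pruning likelihood of the switching model, cached per tree."""

    def __init__(self, idx: TreeIndex, y: np.ndarray, X: np.ndarray):
        self.idx = idx
        self.y = y
        self.X = X
        n = idx.n
        # tips below each node, for internal-branch stationary frequencies;
        # y and X rows are aligned to sorted tip node ids
        self.tip_rows: list[np.ndarray] = [None] * n
        tip_pos = {node: r for r, node in enumerate(sorted(idx.tip_index.values()))}
        below: list[list[int]] = [[] for _ in range(n)]
        for i in idx.postorder:
            if idx.is_tip[i]:
                below[i] = [tip_pos[i]]
            else:
                for c in idx.children[i]:
                    below[i].extend(below[c])
            self.tip_rows[i] = np.array(below[i], dtype=int)

    def loglik(self, beta: np.ndarray, alpha: float) -> float:
        idx = self.idx
        eta = self.X @ beta
        mu_tip = 1.0 / (1.0 + np.exp(-eta))
        # branch-wise stationary frequency of state 1 (tips: their own mu)
        mu_node = np.array([mu_tip[self.tip_rows[i]].mean() for i in range(idx.n)])
        d0 = np.zeros(idx.n)
        d1 = np.zeros(idx.n)
        logscale = 0.0
        for i in idx.postorder:
            if idx.is_tip[i]:
                obs = self.y[self.tip_rows[i][0]]
                d0[i], d1[i] = (1.0, 0.0) if obs == 0 else (0.0, 1.0)
            else:
                m0 = m1 = 1.0
                for c in idx.children[i]:
                    e = math.exp(-alpha * idx.blen[c])
                    pic = mu_node[c]
                    mix = (1.0 - pic) * d0[c] + pic * d1[c]
                    mc0 = e * d0[c] + (1.0 - e) * mix
                    mc1 = e * d1[c] + (1.0 - e) * mix
                    m0 *= mc0
                    m1 *= mc1
                top = m0 if m0 > m1 else m1
                if top <= 0.0:
                    return -np.inf
                d0[i], d1[i] = m0 / top, m1 / top
                logscale += math.log(top)
        root = idx.root
        pi_root = mu_node[root]
        lik = (1.0 - pi_root) * d0[root] + pi_root * d1[root]
        if lik <= 0.0:
            return -np.inf
        return math.log(lik) + logscale

    def penalty(self, beta: np.ndarray) -> float:
        mu = 1.0 / (1.0 + np.exp(-(self.X @ beta)))
        w = mu * (1.0 - mu)
        sign, logdet = np.linalg.slogdet(self.X.T * w @ self.X)
        if sign <= 0:
            return -np.inf
        return 0.5 * logdet


def _design(X, tip_order: list[str]) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        Xd = X.loc[tip_order]
        names = list(Xd.columns)
        mat = Xd.to_numpy(dtype=float)
    elif isinstance(X, dict):
        mat = np.array([[X[t]] for t in tip_order], dtype=float)
        names = ["x"]
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{j+1}" for j in range(mat.shape[1])]
    for j, name in enumerate(names):
        if np.ptp(mat[:, j]) == 0.0:
            raise InvalidInputError(f"predictor {name!r} is constant")
    full = np.column_stack([np.ones(mat.shape[0]), mat])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise InvalidInputError("design matrix is rank deficient")
    return full, ["(Intercept)"] + names


def fit_phyloglm(tree, y, X, max_iter: int = 300) -> PhyloGLMFit:
    """Fit apparency (or any binary tip trait) on tip predictors.

    Parameters
    ----------
    tree
        Rooted tree with branch lengths (dendropy Tree or TreeIndex).
    y
        Binary response per tip: mapping label -> {0, 1}, or a pandas
        Series indexed by label.
    X
        Predictor table (DataFrame indexed by tip label, a mapping for a
        single predictor, or an aligned array).  An intercept column is
        added automatically.

    Standard errors come from the observed information (numerical
    Hessian of the penalized log-likelihood in beta at the optimum,
    alpha held at its estimate); p-values are two-sided normal.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    tip_order = sorted(idx.tip_index, key=lambda lab: idx.tip_index[lab])
    if isinstance(y, pd.Series):
        y = y.to_dict()
    if isinstance(y, dict):
        missing = set(tip_order) - set(y)
        if missing:
            raise InvalidInputError(f"response missing tips {sorted(missing)}")
        yv = np.array([float(y[t]) for t in tip_order])
    else:
        yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise InvalidInputError("response must be binary 0/1")
    if yv.min() == yv.max():
        raise DegenerateInputError("response has a single level")
    Xmat, names = _design(X, tip_order)
    engine = _Engine(idx, yv, Xmat)
    T = max(tree_height_from_index(idx), 1e-12)
    lo, hi = math.log(ALPHA_BOUNDS[0] / T), math.log(ALPHA_BOUNDS[1] / T)
    p = Xmat.shape[1]

    def nll(theta):
        beta, la = theta[:p], min(max(theta[p], lo), hi)
        ll = engine.loglik(beta, math.exp(la)) + engine.penalty(beta)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.zeros(p + 1)
    x0[p] = math.log(1.0 / T)  # start alpha at one switch per tree height
    bounds = [(-30.0, 30.0)] * p + [(lo, hi)]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-11})
    if not np.isfinite(res.fun):
        raise ConvergenceError("penalized likelihood is degenerate", best=res.x)
    theta = res.x
    beta_hat, alpha_hat = theta[:p], math.exp(theta[p])

    # observed information in beta at the optimum (alpha profiled out)
    def nll_beta(beta):
        ll = engine.loglik(beta, alpha_hat) + engine.penalty(beta)
        return -ll if np.isfinite(ll) else 1e12

    h = 1e-4
    H = np.zeros((p, p))
    f0 = nll_beta(beta_hat)
    for a in range(p):
        for b in range(a, p):
            ea, eb = np.eye(p)[a] * h, np.eye(p)[b] * h
            if a == b:
                H[a, a] = (nll_beta(beta_hat + ea) - 2 * f0
                           + nll_beta(beta_hat - ea)) / h**2
            else:
                H[a, b] = H[b, a] = (
                    nll_beta(beta_hat + ea + eb) - nll_beta(beta_hat + ea - eb)
                    - nll_beta(beta_hat - ea + eb) + nll_beta(beta_hat - ea - eb)
                ) / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return PhyloGLMFit(
        coefficients=pd.Series(beta_hat, index=names),
        std_errors=pd.Series(se, index=names),
        z_scores=pd.Series(z, index=names),
        p_values=pd.Series(pvals, index=names),
        alpha=alpha_hat,
        loglik=-res.fun,
        converged=bool(res.success),
        n=len(yv),
    )


def tree_height_from_index(idx: TreeIndex) -> float:
    depth = np.zeros(idx.n)
    for i in idx.preorder:
        if idx.parent[i] >= 0:
            depth[i] = depth[idx.parent[i]] + idx.blen[i]
    return float(depth[np.array([bool(t) for t in idx.is_tip])].max())


def predictor_correlation(tree, x, y) -> tuple[float, float, float]:
    """Phylogenetic logistic regression of binary y on binary x.

    Returns (z, p) for the slope plus the ordinary squared Pearson
    correlation of the two tip vectors (descriptive, non-phylogenetic).
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    tip_order = sorted(idx.tip_index, key=lambda lab: idx.tip_index[lab])
    xv = np.array([float(x[t]) for t in tip_order])
    yv = np.array([float(y[t]) for t in tip_order])
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise DegenerateInputError("binary vector has a single level")
    # identical vectors mean perfect separation; the penalized fit still
    # exists and keeps the slope z finite
    r2 = float(np.corrcoef(xv, yv)[0, 1] ** 2)
    fit = fit_phyloglm(idx, dict(zip(tip_order, yv)),
                       dict(zip(tip_order, xv)))
    slope = fit.z_scores.index[1]
    return float(fit.z_scores[slope]), float(fit.p_values[slope]), r2
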