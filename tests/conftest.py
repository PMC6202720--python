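import itertools

import numpy as np
import pytest

from ontocolor import mkmap, synth
from ontocolor.phyloio import read_tree


@pytest.fixture
def five_tip_tree():
    return read_tree("(((A:0.3,B:0.7):0.4,C:1.1):0.2,(D:0.5,E:0.9):0.6);")


@pytest.fixture
def cherry_tree():
    return read_tree("(A:0.5,B:0.5);")


def random_tree(n_tips: int, seed: int):
    """Seeded birth-death tree rescaled to height 1."""
    return synth.gen_tree(synth.SynthConfig(n_tips=n_tips, seed=seed))


def random_q(k: int, rng, model_class: str = "ARD") -> mkmap.QMatrix:
    n = {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model_class]
    return mkmap.QMatrix.from_rates(k, rng.uniform(0.2, 1.5, n), model_class)


def brute_force_loglik(tree, states, Q, root_prior=None):
    """Exhaustive sum over all internal-node state assignments (oracle)."""
    from scipy.linalg import expm

    idx = mkmap.index_tree(tree)
    k = Q.k
    pi = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    tips = idx.tip_states(states)
    internal = [i for i in range(idx.n) if not idx.is_tip[i]]
    P = {i: expm(Q.matrix * idx.blen[i])
         for i in range(idx.n) if idx.parent[i] >= 0}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = tips.copy()
        for i, a in zip(internal, assign):
            st[i] = a
        p = pi[st[idx.root]]
        for i in range(idx.n):
            if idx.parent[i] >= 0:
                p *= P[i][st[idx.parent[i]], st[i]]
        total += p
    return np.log(total)


def brute_force_marginals(tree, states, Q, root_prior=None):
    """Per-node marginal state probabilities by enumeration (oracle)."""
    from scipy.linalg import expm

    idx = mkmap.index_tree(tree)
    k = Q.k
    pi = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    tips = idx.tip_states(states)
    internal = [i for i in range(idx.n) if not idx.is_tip[i]]
    P = {i: expm(Q.matrix * idx.blen[i])
         for i in range(idx.n) if idx.parent[i] >= 0}
    marg = np.zeros((idx.n, k))
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = tips.copy()
        for i, a in zip(internal, assign):
            st[i] = a
        p = pi[st[idx.root]]
        for i in range(idx.n):
            if idx.parent[i] >= 0:
                p *= P[i][st[idx.parent[i]], st[i]]
        for i in range(idx.n):
            marg[i, st[i]] += p
    return marg / marg.sum(axis=1, keepdims=True)


def firth_logistic(X: np.ndarray, y: np.ndarray, tol=1e-10, max_iter=200):
    """Firth-penalized logistic regression by modified scoring (oracle)."""
    n, p = X.shape
    b = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        inv = np.linalg.inv(info)
        xs = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", xs, inv, xs)
        step = inv @ (X.T @ (y - mu + h * (0.5 - mu)))
        b = b + step
        if np.abs(step).max() < tol:
            break
    return b
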