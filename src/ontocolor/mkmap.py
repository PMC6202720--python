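"""Discrete-character evolution on phylogenies: the Mk model.

Implements the continuous-time Markov model of a k-state character
evolving along a rooted tree with instantaneous rate matrix Q.  Provides

* the pruning (post-order dynamic-programming) log-likelihood,
* maximum-likelihood rate estimation (ER / SYM / ARD parameterisations),
* marginal ancestral state probabilities (combined post-/pre-order pass),
* stochastic character maps — complete state histories along every
  branch, sampled conditional on the tip data — and summaries of them
  (node-state frequencies, counts of independent origins of a state).

Transition probabilities are ``P(t) = expm(Q t)``; the single-rate (ER)
model uses its closed form ``P(t) = e^{-kqt} I + (1 - e^{-kqt}) J/k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import (
    ConvergenceError,
    InvalidRateError,
    InvalidStateError,
    SamplingError,
)
from .phyloio import CharacterMatrix

__all__ = [
    "QMatrix",
    "TreeIndex",
    "index_tree",
    "transition_matrix",
    "mk_loglik",
    "MkFit",
    "fit_mk",
    "AncestralReconstruction",
    "marginal_ancestral",
    "StochasticMap",
    "sample_maps",
    "simulate_mk",
    "OriginCount",
    "count_origins",
    "node_state_summary",
]

_MIN_RATE = 1e-8
_MAX_RATE = 1e3


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QMatrix:
    """A k-state instantaneous rate matrix (rates per unit branch length).

    Rows sum to zero and off-diagonal entries are non-negative.
    `model_class` records the parameterisation: ER (one shared rate),
    SYM (symmetric exchange rates), ARD (all rates different).
    """

    matrix: np.ndarray
    model_class: str = "ARD"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidRateError("Q must be square")
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise InvalidRateError("negative off-diagonal rate")
        if not np.allclose(m.sum(axis=1), 0.0, atol=1e-8):
            raise InvalidRateError("Q rows must sum to zero")
        if self.model_class not in ("ER", "SYM", "ARD"):
            raise InvalidRateError(f"unknown model class {self.model_class!r}")
        if self.model_class == "SYM" and not np.allclose(off, off.T, atol=1e-10):
            raise InvalidRateError("SYM Q must be symmetric off-diagonal")
        if self.model_class == "ER":
            vals = off[~np.eye(m.shape[0], dtype=bool)]
            if not np.allclose(vals, vals[0], atol=1e-12):
                raise InvalidRateError("ER Q must have a single shared rate")
        object.__setattr__(self, "matrix", m)

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def er(cls, k: int, rate: float) -> "QMatrix":
        m = np.full((k, k), rate, dtype=float)
        np.fill_diagonal(m, -(k - 1) * rate)
        return cls(m, "ER")

    @classmethod
    def from_rates(cls, k: int, rates: Sequence[float], model_class: str) -> "QMatrix":
        """Build Q from a flat rate vector in the model's canonical order.

        ER: one rate.  SYM: upper-triangle rates row by row.  ARD: all
        off-diagonal rates row by row.
        """
        rates = np.asarray(rates, dtype=float)
        m = np.zeros((k, k))
        if model_class == "ER":
            m[:] = rates[0]
        elif model_class == "SYM":
            iu = np.triu_indices(k, 1)
            m[iu] = rates
            m.T[iu] = rates
        elif model_class == "ARD":
            m[~np.eye(k, dtype=bool)] = rates
        else:
            raise InvalidRateError(f"unknown model class {model_class!r}")
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, -m.sum(axis=1))
        return cls(m, model_class)

    def n_free_rates(self) -> int:
        k = self.k
        return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[self.model_class]

    def stationary(self) -> np.ndarray:
        """Stationary distribution pi with pi Q = 0, sum(pi) = 1."""
        a = np.vstack([self.matrix.T, np.ones(self.k)])
        b = np.zeros(self.k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def transition_matrix(Q: QMatrix, t: float) -> np.ndarray:
    """P(t) = expm(Q t); closed form for ER."""
    if t < 0:
        raise ValueError("negative time")
    k = Q.k
    if Q.model_class == "ER":
        q = Q.matrix[0, 1] if k > 1 else 0.0
        decay = math.exp(-k * q * t)
        return decay * np.eye(k) + (1.0 - decay) * np.full((k, k), 1.0 / k)
    P = expm(Q.matrix * t)
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Linearised tree
# ---------------------------------------------------------------------------

class TreeIndex:
    """Post-order array view of a dendropy tree for the numeric routines.

    Nodes are numbered in post-order (root last).  `parent[i]` is -1 for
    the root; `blen[i]` is the length of the branch above node i (0 for
    the root); `node_keys[i]` is the tip label for tips and a stable
    ``"node<i>"`` identifier for internal nodes.
    """

    def __init__(self, tree):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        self._ids = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.blen = np.zeros(self.n)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.is_tip = np.zeros(self.n, dtype=bool)
        self.tip_index: dict[str, int] = {}
        self.node_keys: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._ids[id(nd.parent_node)]
                self.parent[i] = p
                self.blen[i] = nd.edge.length or 0.0
                self.children[p].append(i)
            if nd.is_leaf():
                self.is_tip[i] = True
                self.tip_index[nd.taxon.label] = i
                self.node_keys.append(nd.taxon.label)
            else:
                self.node_keys.append(f"node{i}")
        self.root = self.n - 1
        self.postorder = np.arange(self.n)
        self.preorder = self.postorder[::-1]

    def tip_states(self, matrix: CharacterMatrix) -> np.ndarray:
        """State index per node (-1 for internal nodes)."""
        out = np.full(self.n, -1, dtype=int)
        for label, i in self.tip_index.items():
            out[i] = matrix.states[label]
        return out


def index_tree(tree) -> TreeIndex:
    return TreeIndex(tree)


def _root_prior(policy, Q: QMatrix) -> np.ndarray:
    if isinstance(policy, str):
        if policy == "equal":
            return np.full(Q.k, 1.0 / Q.k)
        if policy == "stationary":
            return Q.stationary()
        raise ValueError(f"unknown root prior policy {policy!r}")
    pi = np.asarray(policy, dtype=float)
    if pi.shape != (Q.k,) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-6) or (pi < 0).any():
        raise ValueError("root prior must be a probability vector of length k")
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _partials(idx: TreeIndex, tips: np.ndarray, Q: QMatrix):
    """Post-order conditional likelihoods, per-node rescaled.

    Returns (D, logscale, P) where D[i] is the scaled partial likelihood
    vector of node i, logscale the accumulated log of scaling factors,
    and P[i] the transition matrix across the branch above node i.
    """
    k = Q.k
    D = np.zeros((idx.n, k))
    P = [None] * idx.n
    logscale = 0.0
    for i in idx.postorder:
        if idx.is_tip[i]:
            D[i, tips[i]] = 1.0
        else:
            vec = np.ones(k)
            for c in idx.children[i]:
                vec *= P[c] @ D[c]
            top = vec.max()
            if top <= 0.0:
                return None, -np.inf, P
            D[i] = vec / top
            logscale += math.log(top)
        if idx.parent[i] >= 0:
            P[i] = transition_matrix(Q, idx.blen[i])
    return D, logscale, P


def mk_loglik(tree, states: CharacterMatrix, Q: QMatrix, root_prior="equal") -> float:
    """Log-likelihood of the tip states under the Mk model.

    Post-order pruning with per-node rescaling; `root_prior` is "equal",
    "stationary", or an explicit probability vector.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    pi = _root_prior(root_prior, Q)
    tips = idx.tip_states(states)
    D, logscale, _ = _partials(idx, tips, Q)
    if D is None:
        return -np.inf
    lik = float(pi @ D[idx.root])
    if lik <= 0.0:
        return -np.inf
    return math.log(lik) + logscale


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

@dataclass
class MkFit:
    """Fitted rate matrix with its maximised log-likelihood."""

    Q: QMatrix
    loglik: float
    converged: bool
    boundary: bool = False  # all rates at the lower bound (no observed change)


def fit_mk(tree, states: CharacterMatrix, model_class: str = "ER",
           root_prior="equal", max_iter: int = 500) -> MkFit:
    """Maximum-likelihood Q under the chosen parameterisation.

    Starts from the best point of a coarse log-spaced one-rate grid
    (shared across parameterisations) and refines with L-BFGS-B on log
    rates, bounded in [1e-8, 1e3] per unit branch length. Deterministic
    given inputs.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    k = states.k
    n_rates = {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model_class]
    if len(set(states.states.values())) < 2:
        # no observed change: the MLE sits on the zero-rate boundary
        import warnings
        warnings.warn("no observed character change: rate at lower bound",
                      RuntimeWarning, stacklevel=2)
        Q = QMatrix.from_rates(k, np.full(n_rates, _MIN_RATE), model_class)
        return MkFit(Q=Q, loglik=mk_loglik(idx, states, Q, root_prior),
                     converged=True, boundary=True)

    def nll(logr):
        if not np.all(np.isfinite(logr)):
            return 1e10
        Q = QMatrix.from_rates(k, np.exp(logr), model_class)
        ll = mk_loglik(idx, states, Q, root_prior)
        return -ll if np.isfinite(ll) else 1e10

    # coarse 1-D scan over a shared rate for the starting point
    grid = np.log(np.array([1e-3, 1e-2, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0]))
    best0 = min(grid, key=lambda g: nll(np.full(n_rates, g)))
    x0 = np.full(n_rates, best0)
    bounds = [(math.log(_MIN_RATE), math.log(_MAX_RATE))] * n_rates
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-12})
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise ConvergenceError(f"rate optimisation failed: {res.message}",
                               best=np.exp(res.x))
    rates = np.exp(res.x)
    Q = QMatrix.from_rates(k, rates, model_class)
    boundary = bool((rates <= _MIN_RATE * 1.01).all())
    if boundary:
        import warnings
        warnings.warn("no observed character change: rate at lower bound",
                      RuntimeWarning, stacklevel=2)
    return MkFit(Q=Q, loglik=-res.fun, converged=bool(res.success), boundary=boundary)


# ---------------------------------------------------------------------------
# Marginal ancestral states
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Per-node state probability vectors, post-order aligned with `index`."""

    probs: np.ndarray  # (n_nodes, k)
    index: TreeIndex = field(repr=False)
    state_names: list[str] = field(default_factory=list)

    def by_node(self) -> dict[str, np.ndarray]:
        return {self.index.node_keys[i]: self.probs[i] for i in range(self.index.n)}

    def internal(self) -> np.ndarray:
        return self.probs[~self.index.is_tip]


def marginal_ancestral(tree, states: CharacterMatrix, Q: QMatrix,
                       root_prior="equal") -> AncestralReconstruction:
    """Marginal posterior state probabilities at every node.

    Post-order pass for the conditional (downward) likelihoods, then a
    pre-order pass propagating the complementary (upward) likelihoods;
    the node marginal is the normalised product of the two.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    bind_traits_safe(idx, states)
    pi = _root_prior(root_prior, Q)
    tips = idx.tip_states(states)
    D, logscale, P = _partials(idx, tips, Q)
    if D is None:
        raise InvalidStateError("tip data have zero likelihood under Q")
    k = Q.k
    U = np.zeros((idx.n, k))
    U[idx.root] = pi
    probs = np.zeros((idx.n, k))
    for i in idx.preorder:
        if i != idx.root:
            p = idx.parent[i]
            msg = U[p].copy()
            for b in idx.children[p]:
                if b != i:
                    msg *= P[b] @ D[b]
            U[i] = msg @ P[i]
            s = U[i].sum()
            if s > 0:
                U[i] /= s
        v = U[i] * D[i]
        tot = v.sum()
        probs[i] = v / tot if tot > 0 else np.full(k, 1.0 / k)
    return AncestralReconstruction(probs=probs, index=idx,
                                   state_names=list(states.state_names))


def bind_traits_safe(idx: TreeIndex, states: CharacterMatrix):
    """Raise BindingError if the index's tips and the matrix differ."""
    from .errors import BindingError
    tips = set(idx.tip_index)
    species = set(states.states)
    if tips != species:
        raise BindingError(missing_states=tips - species, extra_species=species - tips)


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------

@dataclass
class StochasticMap:
    """One full sampled character history.

    `node_states[i]` is the sampled state at node i; `segments[i]` lists
    (state, dwell length) pairs along the branch above node i, ordered
    from the parent end; segment lengths sum to the branch length and
    adjacent segments differ in state.
    """

    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]
    index: TreeIndex = field(repr=False)
    k: int = 0  # number of states in the generating model

    def n_changes(self) -> int:
        return sum(len(seg) - 1 for seg in self.segments if seg)


def _sample_path(rng: np.random.Generator, Q: np.ndarray, a: int, b: int,
                 t: float, max_attempts: int) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on (0, t) from state a to state b.

    Rejection sampling: unconditional forward simulation when a == b;
    when a != b the first jump time is drawn from the exponential
    truncated to (0, t) so every attempt contains at least one change.
    """
    k = Q.shape[0]
    if t <= 0.0:
        if a != b:
            raise SamplingError("state change across zero-length branch")
        return [(a, 0.0)]
    exit_rates = -np.diag(Q)
    jump = Q / np.where(exit_rates[:, None] > 0, exit_rates[:, None], 1.0)
    np.fill_diagonal(jump, 0.0)
    for _ in range(max_attempts):
        path = [(a, 0.0)]
        state, elapsed = a, 0.0
        if a != b:
            r = exit_rates[a]
            if r <= 0.0:
                raise SamplingError("absorbing start state cannot reach endpoint")
            u = rng.random()
            tau = -math.log1p(-u * (1.0 - math.exp(-r * t))) / r
            nxt = rng.choice(k, p=jump[a])
            path[-1] = (a, tau)
            path.append((nxt, 0.0))
            state, elapsed = nxt, tau
        while True:
            r = exit_rates[state]
            tau = math.inf if r <= 0.0 else rng.exponential(1.0 / r)
            if elapsed + tau >= t:
                path[-1] = (state, t - elapsed)
                break
            nxt = rng.choice(k, p=jump[state])
            path[-1] = (state, tau)
            path.append((nxt, 0.0))
            elapsed += tau
            state = nxt
        if state == b:
            return path
    raise SamplingError(
        f"endpoint-conditioned path rejected {max_attempts} times "
        f"(branch length {t}, states {a}->{b}); consider a larger rate bound")


def sample_maps(tree, states: CharacterMatrix, Q: QMatrix, root_prior="equal",
                nsim: int = 2000, seed: int | None = None,
                max_attempts: int = 10**6) -> list[StochasticMap]:
    """Draw `nsim` stochastic character maps conditional on the tip data.

    Node states are sampled pre-order from their conditional
    distributions given the sampled parent state and the subtree data;
    branch histories are then filled in by endpoint-conditioned
    rejection sampling of the CTMC. Reproducible given `seed`.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    bind_traits_safe(idx, states)
    pi = _root_prior(root_prior, Q)
    tips = idx.tip_states(states)
    D, _, P = _partials(idx, tips, Q)
    if D is None:
        raise InvalidStateError("tip data have zero likelihood under Q")
    rng = np.random.default_rng(seed)
    root_w = pi * D[idx.root]
    root_w = root_w / root_w.sum()
    maps = []
    for _ in range(nsim):
        node_states = np.full(idx.n, -1, dtype=int)
        node_states[idx.root] = rng.choice(Q.k, p=root_w)
        segments: list[list[tuple[int, float]]] = [[] for _ in range(idx.n)]
        for i in idx.preorder:
            if i == idx.root:
                continue
            s = node_states[idx.parent[i]]
            w = P[i][s] * D[i]
            tot = w.sum()
            if tot <= 0.0:
                raise SamplingError("zero conditional mass at a node")
            j = int(rng.choice(Q.k, p=w / tot))
            node_states[i] = j
            segments[i] = _sample_path(rng, Q.matrix, s, j, idx.blen[i],
                                       max_attempts)
        maps.append(StochasticMap(node_states=node_states, segments=segments,
                                  index=idx, k=Q.k))
    return maps


def simulate_mk(tree, Q: QMatrix, root_prior="equal",
                seed: int | None = None, root_state: int | None = None) -> StochasticMap:
    """Unconditional forward simulation of the Mk process along the tree.

    Returns the full true history (for generator ground truth); tip
    states are `map.node_states[i]` at tip nodes.
    """
    idx = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    pi = _root_prior(root_prior, Q)
    rng = np.random.default_rng(seed)
    k = Q.k
    exit_rates = -np.diag(Q.matrix)
    jump = Q.matrix / np.where(exit_rates[:, None] > 0, exit_rates[:, None], 1.0)
    np.fill_diagonal(jump, 0.0)
    node_states = np.full(idx.n, -1, dtype=int)
    node_states[idx.root] = root_state if root_state is not None else rng.choice(k, p=pi)
    segments: list[list[tuple[int, float]]] = [[] for _ in range(idx.n)]
    for i in idx.preorder:
        if i == idx.root:
            continue
        s = node_states[idx.parent[i]]
        t = idx.blen[i]
        path = [(s, 0.0)]
        state, elapsed = s, 0.0
        while True:
            r = exit_rates[state]
            tau = math.inf if r <= 0.0 else rng.exponential(1.0 / r)
            if elapsed + tau >= t:
                path[-1] = (state, t - elapsed)
                break
            nxt = int(rng.choice(k, p=jump[state]))
            path[-1] = (state, tau)
            path.append((nxt, 0.0))
            elapsed += tau
            state = nxt
        segments[i] = path
        node_states[i] = state
    return StochasticMap(node_states=node_states, segments=segments, index=idx,
                         k=Q.k)


# ---------------------------------------------------------------------------
# Map summaries
# ---------------------------------------------------------------------------

@dataclass
class OriginCount:
    """Distribution, across sampled maps, of independent origins of a state."""

    state: int
    counts: np.ndarray  # one integer per map
    modal_count: int

    def distribution(self) -> dict[int, int]:
        vals, freq = np.unique(self.counts, return_counts=True)
        return {int(v): int(f) for v, f in zip(vals, freq)}


def count_origins(maps: list[StochasticMap], target_state: int,
                  count_root: bool = True) -> OriginCount:
    """Number of transitions into `target_state` per sampled map.

    A transition is a segment boundary entering the target state on any
    branch; the root counts as one origin when it is in the target state
    (an evolutionary gain predating the clade), controlled by
    `count_root`.
    """
    if not maps:
        raise ValueError("no maps given")
    idx = maps[0].index
    k = maps[0].k or int(max(m.node_states.max() for m in maps)) + 1
    if not 0 <= target_state < k:
        raise InvalidStateError(f"state {target_state} outside [0, {k})")
    counts = np.zeros(len(maps), dtype=int)
    for m, smap in enumerate(maps):
        n = 0
        if count_root and smap.node_states[idx.root] == target_state:
            n += 1
        for seg in smap.segments:
            for j in range(1, len(seg)):
                if seg[j][0] == target_state and seg[j - 1][0] != target_state:
                    n += 1
        counts[m] = n
    vals, freq = np.unique(counts, return_counts=True)
    modal = int(vals[np.argmax(freq)])
    return OriginCount(state=target_state, counts=counts, modal_count=modal)


def node_state_summary(maps: list[StochasticMap],
                       state_names: Sequence[str] | None = None) -> AncestralReconstruction:
    """Empirical node-state frequencies across maps (the pie-chart values)."""
    if not maps:
        raise ValueError("no maps given")
    idx = maps[0].index
    k = int(max(m.node_states.max() for m in maps)) + 1
    if state_names is not None:
        k = max(k, len(state_names))
    freq = np.zeros((idx.n, k))
    for smap in maps:
        freq[np.arange(idx.n), smap.node_states] += 1.0
    freq /= len(maps)
    return AncestralReconstruction(probs=freq, index=idx,
                                   state_names=list(state_names or []))
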