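"""Mk models on trees: pruning likelihood, ML rates, marginal ancestral states.

The transition matrix is symmetric ("ER": one rate for every pair, "SYM": one
rate per unordered pair).  Marginal reconstructions use the re-rooting scheme:
the marginal at a node is proportional to the product of the conditional
likelihoods flowing in from every direction, times the root prior, which for a
symmetric Q equals the exact joint-enumeration marginal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .trees import PhyloTree

__all__ = ["MkModel", "ASRResult", "mk_loglik", "fit_mk", "marginal_asr", "ml_states"]

_PROB_CLAMP = -1e-12


@dataclass
class MkModel:
    state_labels: list[str]
    Q: np.ndarray

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.state_labels)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match state labels")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.Q, self.Q.T, atol=1e-12):
            raise ValueError("Q must be symmetric")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-12 * (1 + np.abs(self.Q).max())):
            raise ValueError("rows of Q must sum to 0")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @classmethod
    def er(cls, state_labels: Sequence[str], q: float) -> "MkModel":
        k = len(state_labels)
        Q = np.full((k, k), q)
        np.fill_diagonal(Q, -q * (k - 1))
        return cls(list(state_labels), Q)

    @classmethod
    def sym(cls, state_labels: Sequence[str], rates: Sequence[float]) -> "MkModel":
        """One rate per unordered pair, in lexicographic (i, j) order, i < j."""
        k = len(state_labels)
        Q = np.zeros((k, k))
        it = iter(rates)
        for i in range(k):
            for j in range(i + 1, k):
                r = next(it)
                Q[i, j] = Q[j, i] = r
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(list(state_labels), Q)

    def _eig(self):
        if not hasattr(self, "_eig_cache"):
            object.__setattr__(self, "_eig_cache", np.linalg.eigh(self.Q))
        return self._eig_cache

    def transition_matrix(self, t: float) -> np.ndarray:
        # symmetric Q: exponentiate via the (cached) eigendecomposition
        w, V = self._eig()
        P = (V * np.exp(w * t)) @ V.T
        P[(P < 0) & (P > _PROB_CLAMP)] = 0.0
        if np.any(P < 0):
            P = np.clip(P, 0.0, None)
        return P


@dataclass
class ASRResult:
    state_labels: list[str]
    node_marginals: dict[int, np.ndarray]
    scaled_loglik: float

    def to_csv(self) -> str:
        lines = ["node_id," + ",".join(f"p_{s}" for s in self.state_labels)]
        for nid in sorted(self.node_marginals):
            probs = ",".join(f"{p:.10g}" for p in self.node_marginals[nid])
            lines.append(f"{nid},{probs}")
        return "\n".join(lines) + "\n"


def _tip_vector(model: MkModel, state: str) -> np.ndarray:
    try:
        i = model.state_labels.index(state)
    except ValueError:
        raise ValueError(f"unknown tip state {state!r}") from None
    v = np.zeros(model.n_states)
    v[i] = 1.0
    return v


def _branch_transition_matrices(tree: PhyloTree, model: MkModel) -> dict[int, np.ndarray]:
    """P(t_b) for every branch in one batched eigen-exponential."""
    nodes = [n for n in tree.nodes if n.parent is not None]
    w, V = model._eig()
    lengths = np.array([n.length for n in nodes])
    E = np.exp(np.outer(lengths, w))
    P = np.einsum("ik,bk,jk->bij", V, E, V)
    np.clip(P, 0.0, None, out=P)
    return {n.id: P[i] for i, n in enumerate(nodes)}


def _downward_pass(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    model: MkModel,
    P: dict[int, np.ndarray] | None = None,
) -> tuple[dict[int, np.ndarray], float]:
    """Felsenstein pruning with per-node scaling; returns (partials, log-scale)."""
    if P is None:
        P = _branch_transition_matrices(tree, model)
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in tip_states:
                raise ValueError(f"no state for tip {node.label!r}")
            partials[node.id] = _tip_vector(model, tip_states[node.label])
        else:
            L = np.ones(model.n_states)
            for child in node.children:
                L = L * (P[child.id] @ partials[child.id])
            s = L.max()
            if s <= 0:
                raise ValueError("zero likelihood at an internal node")
            log_scale += np.log(s)
            partials[node.id] = L / s
    return partials, log_scale


def mk_loglik(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    model: MkModel,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of discrete tip states under the Mk model (pruning)."""
    if root_prior is None:
        root_prior = np.full(model.n_states, 1.0 / model.n_states)
    partials, log_scale = _downward_pass(tree, tip_states, model)
    L = float(root_prior @ partials[tree.root.id])
    if L <= 0:
        return -np.inf
    return np.log(L) + log_scale


def fit_mk(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    flavor: str = "ER",
    state_labels: Sequence[str] | None = None,
) -> MkModel:
    """ML rate estimation on the log scale; Brent for ER, multi-start NM for SYM."""
    if state_labels is None:
        state_labels = sorted(set(tip_states.values()))
    state_labels = list(state_labels)
    if len(set(tip_states.values())) < 2:
        raise ValueError("all tips share one state; rate is unidentifiable")
    if flavor not in ("ER", "SYM"):
        raise ValueError(f"unknown flavor {flavor!r}")
    n_pairs = len(state_labels) * (len(state_labels) - 1) // 2

    if flavor == "ER" or n_pairs == 1:

        def nll(logq: float) -> float:
            return -mk_loglik(tree, tip_states, MkModel.er(state_labels, np.exp(logq)))

        grid = np.linspace(-10, 6, 12)
        vals = [nll(g) for g in grid]
        i = int(np.argmin(vals))
        res = minimize_scalar(nll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, 11)]),
                              method="bounded", options={"xatol": 1e-8})
        best_x = res.x if res.fun <= vals[i] else grid[i]
        return MkModel.er(state_labels, float(np.exp(best_x)))

    def nll_vec(logr: np.ndarray) -> float:
        return -mk_loglik(tree, tip_states, MkModel.sym(state_labels, np.exp(logr)))

    rng = np.random.default_rng(0)
    best = None
    starts = [np.zeros(n_pairs), np.full(n_pairs, -2.0),
              rng.uniform(-4, 2, n_pairs)]
    for x0 in starts:
        res = minimize(nll_vec, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    return MkModel.sym(state_labels, np.exp(best.x))


def marginal_asr(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    model: MkModel,
    root_prior: np.ndarray | None = None,
) -> ASRResult:
    """Exact marginal posteriors at internal nodes (two-pass belief propagation)."""
    if root_prior is None:
        root_prior = np.full(model.n_states, 1.0 / model.n_states)
    P = _branch_transition_matrices(tree, model)
    partials, log_scale = _downward_pass(tree, tip_states, model, P=P)
    root_L = float(root_prior @ partials[tree.root.id])
    loglik = np.log(root_L) + log_scale

    # upward messages: up[v] = prior x evidence from everywhere outside v's subtree
    up: dict[int, np.ndarray] = {tree.root.id: np.asarray(root_prior, dtype=float)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        child_msgs = {c.id: P[c.id] @ partials[c.id] for c in node.children}
        for child in node.children:
            sib = up[node.id].copy()
            for other in node.children:
                if other is not child:
                    sib = sib * child_msgs[other.id]
            msg = P[child.id].T @ sib  # symmetric P; transpose kept for clarity
            s = msg.max()
            up[child.id] = msg / s if s > 0 else msg

    marginals: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        if node.is_tip:
            continue
        m = up[node.id] * partials[node.id]
        total = m.sum()
        if total <= 0:
            raise ValueError(f"zero marginal at node {node.id}")
        marginals[node.id] = m / total
    return ASRResult(list(model.state_labels), marginals, loglik)


def ml_states(asr: ASRResult, tree: PhyloTree, tiebreak: str = "parent") -> dict[int, str]:
    """Argmax state per internal node; exact ties resolved toward the parent
    state ("parent") or the first label ("first")."""
    if tiebreak not in ("parent", "first"):
        raise ValueError(f"unknown tiebreak {tiebreak!r}")
    out: dict[int, str] = {}
    for node in tree.preorder():
        if node.is_tip:
            continue
        m = asr.node_marginals[node.id]
        top = m.max()
        winners = [i for i, v in enumerate(m) if v == top]
        if len(winners) == 1:
            out[node.id] = asr.state_labels[winners[0]]
        elif tiebreak == "parent" and node.parent is not None and node.parent.id in out:
            parent_state = out[node.parent.id]
            if parent_state in (asr.state_labels[i] for i in winners):
                out[node.id] = parent_state
            else:
                out[node.id] = asr.state_labels[winners[0]]
        else:
            out[node.id] = asr.state_labels[winners[0]]
    return out
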