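import numpy as np
import pytest

from macroevo.synthetic_data import simulate_yule_tree
from macroevo.trees import PhyloTree


@pytest.fixture(scope="session")
def tree64() -> PhyloTree:
    return simulate_yule_tree(64, target_height=7.16, seed=1)


@pytest.fixture(scope="session")
def tree20() -> PhyloTree:
    return simulate_yule_tree(20, target_height=1.0, seed=2)


def random_tree(rng: np.random.Generator, n_tips: int, height: float = 1.0) -> PhyloTree:
    return simulate_yule_tree(
        n_tips, target_height=height, seed=int(rng.integers(2**31 - 1))
    )


# -- independent oracles ----------------------------------------------


def root_to_tip_paths(tree: PhyloTree) -> dict[str, list]:
    """Tip label -> list of (node, branch length) edges from the root."""
    paths = {}
    for tip in tree.tips:
        edges = []
        node = tip
        while node.parent is not None:
            edges.append((node, node.length))
            node = node.parent
        paths[tip.label] = list(reversed(edges))
    return paths


def brute_force_shared_time(tree: PhyloTree) -> np.ndarray:
    """Shared path length between root-to-tip paths, edge by edge."""
    paths = root_to_tip_paths(tree)
    taxa = tree.taxa
    n = len(taxa)
    out = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            shared = 0.0
            for (na, la), (nb, lb) in zip(paths[a], paths[b]):
                if na is not nb:
                    break
                shared += la
            out[i, j] = shared
    return out


def mvn_logpdf_dense(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Plain dense-inverse multivariate normal log density."""
    n = len(y)
    resid = y - mean
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + resid @ inv @ resid))


def mk_enumeration(tree: PhyloTree, tip_states, model, root_prior=None):
    """Exhaustive sum over internal-node state assignments.

    Returns (loglik, marginals dict node id -> vector)."""
    from itertools import product

    k = model.n_states
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    internals = [n for n in tree.nodes if not n.is_tip]
    P = {n.id: model.transition_matrix(n.length) for n in tree.nodes if n.parent}
    idx = {s: i for i, s in enumerate(model.state_labels)}
    total = 0.0
    marg = {n.id: np.zeros(k) for n in internals}
    for assign in product(range(k), repeat=len(internals)):
        states = {n.id: s for n, s in zip(internals, assign)}
        for t in tree.tips:
            states[t.id] = idx[tip_states[t.label]]
        lik = root_prior[states[tree.root.id]]
        for node in tree.nodes:
            if node.parent is not None:
                lik *= P[node.id][states[node.parent.id], states[node.id]]
        total += lik
        for n in internals:
            marg[n.id][states[n.id]] += lik
    for n in internals:
        marg[n.id] /= total
    return np.log(total), marg
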