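"""Seeded generators standing in for the study's unavailable raw data.

Everything here is deterministic given a seed: pure-birth trees, node-age
jittered "posterior" samples, Mk regime histories, traits under any of the
model scenarios, min/max range tables with missingness, and a climate matrix
driven by two latent factors (an altitude-like axis loading on temperature
variables and elevation with opposite signs, and a latitude-like axis on
which latitude and longitude load with opposite signs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gauss_models import ModelConfig, ModelParams, _Cache, _seg_var_integral, _state_vectors
from .mk_asr import MkModel
from .trees import Node, PhyloTree, RegimePainting, parse_newick, write_newick

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_posterior_sample",
    "simulate_mk_states",
    "simulate_traits",
    "simulate_traits_matrix",
    "simulate_species_table",
]

MORPH_TRAITS = [
    "plant_height",
    "leaf_length",
    "leaf_width",
    "calyx_width",
    "corolla_width",
    "corolla_length",
]

CLIMATE_VARS = ["LAT", "LONG", "ALT"] + [f"BIO{i}" for i in range(1, 20)]

# (factor-1 loading, factor-2 loading) per climate variable; the sign pattern
# mirrors an altitude-driven first axis and a latitude-driven second axis.
CLIMATE_LOADINGS: dict[str, tuple[float, float]] = {
    "LAT": (0.06, 0.88), "LONG": (0.06, -0.82), "ALT": (-0.92, 0.11),
    "BIO1": (0.89, -0.19), "BIO2": (-0.48, -0.54), "BIO3": (-0.03, 0.69),
    "BIO4": (0.02, -0.82), "BIO5": (0.86, -0.33), "BIO6": (0.92, 0.09),
    "BIO7": (-0.41, -0.77), "BIO8": (0.88, -0.23), "BIO9": (0.92, -0.08),
    "BIO10": (0.90, -0.24), "BIO11": (0.89, -0.10), "BIO12": (0.82, 0.07),
    "BIO13": (0.71, -0.14), "BIO14": (0.71, 0.26), "BIO15": (-0.36, -0.46),
    "BIO16": (0.71, -0.15), "BIO17": (0.72, 0.26), "BIO18": (0.70, -0.14),
    "BIO19": (0.68, 0.30),
}


@dataclass
class SimulationConfig:
    n_tips: int = 63
    birth_rate: float = 1.0
    target_height: float = 7.16
    mk_rate_habitat: float = 0.15
    mk_rate_geo: float = 0.15
    missing_rate: float = 0.06
    range_spread: float = 0.25
    jitter_sd: float = 0.05
    n_posterior: int = 100
    slice_age: float = 2.6
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


# -- trees -------------------------------------------------------------


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    target_height: float | None = None,
    seed: int = 0,
) -> PhyloTree:
    """Pure-birth tree conditioned on ``n_tips``, optionally rescaled to a
    fixed root height."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = Node()
    active: list[tuple[Node, float]] = []  # (node, birth time)
    t = 0.0
    for _ in range(2):
        c = Node()
        c.parent = root
        root.children.append(c)
        active.append((c, 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, born = active.pop(i)
        node.length = t - born
        for _ in range(2):
            c = Node()
            c.parent = node
            node.children.append(c)
            active.append((c, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    counter = 1
    for node, born in active:
        node.length = t - born
        node.label = f"t{counter}"
        counter += 1
    tree = PhyloTree(root)
    if target_height is not None:
        scale = target_height / tree.root_height
        for node in tree.nodes:
            if node.length is not None:
                node.length *= scale
        tree = PhyloTree(tree.root)
    # deterministic tip labelling independent of rng consumption order
    return tree


def simulate_posterior_sample(
    tree: PhyloTree,
    n_trees: int = 100,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> list[PhyloTree]:
    """Jitter internal node ages lognormally, keeping topology, taxa and root
    height fixed, and re-imposing ultrametry (tips stay at age 0)."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if jitter_sd == 0:
        return [parse_newick(write_newick(tree)) for _ in range(n_trees)]
    out = []
    H = tree.root_height
    for _ in range(n_trees):
        t = parse_newick(write_newick(tree))
        new_age: dict[int, float] = {t.root.id: H}
        for node in t.preorder():
            if node is t.root or node.is_tip:
                continue
            age = H - node.depth
            parent_age = new_age[node.parent.id]
            proposal = 0.0
            for _ in range(20):  # bounded retries before clamping
                proposal = age * math.exp(jitter_sd * rng.standard_normal())
                if 0.0 < proposal < parent_age:
                    break
            new_age[node.id] = min(max(proposal, 1e-9), parent_age * (1 - 1e-9))
        for node in t.preorder():
            if node is t.root:
                continue
            child_age = new_age.get(node.id, 0.0)
            node.length = new_age[node.parent.id] - child_age
        out.append(PhyloTree(t.root))
    return out


# -- discrete histories ------------------------------------------------


def simulate_mk_states(
    tree: PhyloTree,
    model: MkModel,
    root_state: str,
    seed: int = 0,
) -> tuple[dict[str, str], dict[int, str], RegimePainting]:
    """Exact CTMC simulation along every branch; returns the full history as
    (tip states, internal node states, true segment painting)."""
    rng = np.random.default_rng(seed)
    labels = model.state_labels
    idx = {s: i for i, s in enumerate(labels)}
    Q = model.Q
    node_states: dict[int, str] = {tree.root.id: root_state}
    tip_states: dict[str, str] = {}
    segments: dict[int, list[tuple[float, float, str]]] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        state = idx[node_states[node.parent.id]]
        top = tree.node_age(node.parent)
        bottom = tree.node_age(node)
        age = top
        segs: list[tuple[float, float, str]] = []
        while True:
            rate = -Q[state, state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if age - wait <= bottom:
                segs.append((age, bottom, labels[state]))
                break
            segs.append((age, age - wait, labels[state]))
            age -= wait
            probs = Q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(len(labels), p=probs))
        segments[node.id] = segs
        if node.is_tip:
            tip_states[node.label] = labels[state]
        else:
            node_states[node.id] = labels[state]
    painting = RegimePainting(list(labels), segments)
    return tip_states, node_states, painting


# -- continuous traits -------------------------------------------------


def simulate_traits_matrix(
    tree: PhyloTree,
    config: ModelConfig,
    params: ModelParams,
    seed: int = 0,
    nsim: int = 1,
    root_mode: str = "fixed",
) -> np.ndarray:
    """``nsim`` independent trait vectors (rows) by exact recursive simulation
    root -> tips; each segment applies the pull-process transition density."""
    rng = np.random.default_rng(seed)
    cache = _Cache(tree, config)
    alpha, sigma2, r = _state_vectors(cache, config, params)
    root_idx = cache.state_index[cache.root_state]
    theta = np.zeros(len(cache.states))
    for i, s in enumerate(cache.states):
        if alpha[i] > 0:
            theta[i] = params.theta_for(s)
    if root_mode == "stationary":
        if alpha[root_idx] <= 0:
            raise ValueError("stationary root requires pull in the root regime")
        sd0 = math.sqrt(sigma2[root_idx] / (2 * alpha[root_idx]))
        x_root = theta[root_idx] + sd0 * rng.standard_normal(nsim)
    else:
        if params.x0 is not None:
            x0 = params.x0
        elif np.any(alpha > 0):
            x0 = params.theta_for(cache.root_state)
        else:
            raise ValueError("x0 required for models without pull")
        x_root = np.full(nsim, float(x0))
    values: dict[int, np.ndarray] = {tree.root.id: x_root}
    for node in tree.preorder():
        if node is tree.root:
            continue
        x = values[node.parent.id]
        for a, b, k in cache.segments[node.id]:
            d = math.exp(-alpha[k] * (b - a))
            var = _seg_var_integral(sigma2[k], alpha[k], r, a, b)
            x = theta[k] + (x - theta[k]) * d
            if var > 0:
                x = x + math.sqrt(var) * rng.standard_normal(nsim)
        values[node.id] = x
    out = np.empty((nsim, tree.n_tips))
    for j, tip in enumerate(tree.tips):
        out[:, j] = values[tip.id]
    return out


def simulate_traits(
    tree: PhyloTree,
    config: ModelConfig,
    params: ModelParams,
    seed: int = 0,
    root_mode: str = "fixed",
) -> dict[str, float]:
    row = simulate_traits_matrix(tree, config, params, seed=seed, nsim=1,
                                 root_mode=root_mode)[0]
    return dict(zip(tree.taxa, row))


# -- species tables ----------------------------------------------------


def simulate_species_table(
    tree: PhyloTree,
    traits: pd.DataFrame,
    missing_rate: float = 0.06,
    range_spread: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min/max range table (original scale) and a climate matrix.

    ``traits`` holds per-species log-scale means (rows = species).  Ranges are
    ``exp(mean -/+ h)`` with lognormal half-range ``h``; cells are masked
    i.i.d. at ``missing_rate`` (never a whole row or column).  The climate
    matrix mixes two tree-structured latent factors through the fixed loading
    pattern plus unit noise.
    """
    rng = np.random.default_rng(seed)
    species = list(traits.index)
    cols = {}
    mask_cols = []
    for trait in traits.columns:
        h = range_spread * np.exp(0.5 * rng.standard_normal(len(species)))
        cols[f"{trait}_min"] = np.exp(traits[trait].to_numpy() - h)
        cols[f"{trait}_max"] = np.exp(traits[trait].to_numpy() + h)
        mask_cols += [f"{trait}_min", f"{trait}_max"]
    ranges = pd.DataFrame(cols, index=pd.Index(species, name="species"))
    if missing_rate > 0:
        mask = rng.random(ranges.shape) < missing_rate
        for i in range(mask.shape[0]):  # keep every row partially observed
            if mask[i].all():
                mask[i, rng.integers(mask.shape[1])] = False
        for j in range(mask.shape[1]):
            if mask[:, j].all():
                mask[rng.integers(mask.shape[0]), j] = False
        ranges = ranges.mask(mask)

    # climate: two phylogenetically structured latent factors
    bm = ModelConfig("BM", "BM1")
    f = simulate_traits_matrix(tree, bm, ModelParams(sigma2=1.0, x0=0.0),
                               seed=seed + 1, nsim=2)
    f = (f - f.mean(axis=1, keepdims=True)) / f.std(axis=1, keepdims=True)
    order = [tree.taxa.index(s) for s in species]
    noise_scale = 0.3
    climate = {}
    for var in CLIMATE_VARS:
        l1, l2 = CLIMATE_LOADINGS[var]
        climate[var] = (
            l1 * f[0, order] + l2 * f[1, order]
            + noise_scale * rng.standard_normal(len(species))
        )
    climate_df = pd.DataFrame(climate, index=pd.Index(species, name="species"))
    return ranges, climate_df
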