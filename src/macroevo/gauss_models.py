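"""Gaussian trait-evolution models on regime-painted trees.

All eleven comparison scenarios are expressed as one time-inhomogeneous
Gaussian process.  Along each lineage, painted segments carry a pull strength
``alpha_s`` (0 for Brownian segments), a diffusion rate ``sigma2_s`` which may
decay exponentially in process time (``sigma2_s * exp(r t)``, the early-burst
form), and an optimum ``theta_s`` for segments with pull.  Writing
``A_i(s, t)`` for the integrated pull along lineage ``i`` between process
times ``s`` and ``t``:

* tip mean  ``m_i = x0 e^{-A_i(0,T)} + sum_s theta_s (e^{-A_i(b_s,T)} - e^{-A_i(a_s,T)})``
* tip covariance ``cov(i,j) = V(t_m) e^{-A_i(t_m,T)} e^{-A_j(t_m,T)}`` with
  ``V(t) = integral_0^t sigma2(u) e^{-2A(u,t)} du`` accumulated along the
  shared root path and ``t_m`` the MRCA time.

Every per-segment integral is closed form, so moments are exact.  Fitting
profiles the linear mean parameters by GLS and the global rate scale in
closed form; only pull strength, burst exponent and rate ratios are searched
numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize, minimize_scalar

from .trees import (
    PhyloTree,
    RegimePainting,
    paint_time_slice,
    single_state_painting,
)

__all__ = [
    "ModelConfig",
    "ModelParams",
    "GaussianMoments",
    "FitResult",
    "ComparisonTable",
    "SCENARIO_ORDER",
    "trait_moments",
    "loglik",
    "fit_model",
    "aicc",
    "half_life",
    "stationary_variance",
    "build_scenarios",
    "compare_scenarios",
]

SCENARIO_ORDER = [
    "BM1",
    "EB",
    "OU1",
    "SHIFT",
    "ER",
    "BMM_Regime",
    "OUM_Regime",
    "BMM_Clade",
    "OUM_Clade",
    "BMM_Geo",
    "OUM_Geo",
]

_JITTER = 1e-10


@dataclass
class ModelConfig:
    """One of the 11 comparison scenarios.

    ``model_class`` is BM, OU, EB, SHIFT or ER; multi-regime variants differ
    only in the painting they carry.  SHIFT and ER require ``slice_age``.
    """

    model_class: str
    scenario_name: str
    painting: RegimePainting | None = None
    slice_age: float | None = None
    er_free_post_sigma: bool = False

    def __post_init__(self):
        if self.model_class not in ("BM", "OU", "EB", "SHIFT", "ER"):
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.model_class in ("SHIFT", "ER") and self.slice_age is None:
            raise ValueError(f"{self.model_class} requires slice_age")


@dataclass
class ModelParams:
    """Parameter values; ``sigma2``/``theta`` may be per-regime mappings."""

    sigma2: float | Mapping[str, float]
    alpha: float = 0.0
    theta: float | Mapping[str, float] | None = None
    x0: float | None = None
    r: float = 0.0

    def sigma2_for(self, state: str) -> float:
        if isinstance(self.sigma2, Mapping):
            return float(self.sigma2[state])
        return float(self.sigma2)

    def theta_for(self, state: str) -> float:
        if self.theta is None:
            raise ValueError("theta not set")
        if isinstance(self.theta, Mapping):
            return float(self.theta[state])
        return float(self.theta)


@dataclass
class GaussianMoments:
    taxa: list[str]
    mean: np.ndarray
    cov: np.ndarray


@dataclass
class FitResult:
    config: ModelConfig
    params: ModelParams
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    n_restarts: int = 0

    def __post_init__(self):
        expected = aicc(self.loglik, self.k, self.n)
        if not math.isclose(self.aicc, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("aicc inconsistent with loglik/k/n")


# -- closed-form pieces ------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (half-life is infinite at 0)")
    return math.log(2.0) / alpha


def stationary_variance(sigma2: float, alpha: float) -> float:
    """Equilibrium variance sigma^2 / (2 alpha) of the pull process."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return sigma2 / (2.0 * alpha)


def _seg_var_integral(sigma2: float, alpha: float, r: float, a: float, b: float) -> float:
    """integral_a^b sigma2 e^{r u} e^{-2 alpha (b-u)} du, exactly."""
    if b <= a:
        return 0.0
    c = r + 2.0 * alpha
    if abs(c) < 1e-14:
        return sigma2 * math.exp(-2.0 * alpha * b) * (b - a)
    if abs(c * (b - a)) < 1e-9:
        # expm1 guards catastrophic cancellation for tiny exponents
        return sigma2 * math.exp(r * a - 2.0 * alpha * (b - a)) * math.expm1(c * (b - a)) / c
    # stable form: r*b <= 0 and r*a - 2 alpha (b-a) <= 0, so nothing overflows
    return sigma2 * (math.exp(r * b) - math.exp(r * a - 2.0 * alpha * (b - a))) / c


# -- painted-tree cache ------------------------------------------------


class _Cache:
    """Per-(tree, config) segment table in process time plus index structures."""

    def __init__(self, tree: PhyloTree, config: ModelConfig):
        self.tree = tree
        self.config = config
        if config.model_class in ("SHIFT", "ER"):
            painting = paint_time_slice(tree, config.slice_age)
        elif config.painting is not None:
            painting = config.painting
        else:
            painting = single_state_painting(tree)
        self.painting = painting
        self.states = list(painting.states)
        self.state_index = {s: i for i, s in enumerate(self.states)}
        H = tree.root_height
        # per non-root node: ordered (t0, t1, state_idx) in process time
        self.segments: dict[int, list[tuple[float, float, int]]] = {}
        used = set()
        for node in tree.nodes:
            if node is tree.root:
                continue
            segs = painting.segments.get(node.id)
            if segs is None:
                raise ValueError(f"branch {node.id} unpainted for {config.scenario_name}")
            self.segments[node.id] = [
                (H - sa, H - ea, self.state_index[st]) for sa, ea, st in segs
            ]
            used.update(st for _, _, st in segs)
        self.used_states = [s for s in self.states if s in used]
        self.tipsets = tree.tip_sets()
        self.tip_depth = np.array([t.depth for t in tree.tips])
        # root regime = state at the oldest end of the first root-child branch
        first_child = tree.root.children[0]
        self.root_state = self.states[self.segments[first_child.id][0][2]]
        self.tip_ids = np.array([t.id for t in tree.tips])
        # flat pair index: each unordered tip pair appears once, at its MRCA
        pi, pj, pm = [], [], []
        for node in tree.preorder():
            if node.is_tip:
                continue
            for a_i, a in enumerate(node.children):
                for b in node.children[a_i + 1 :]:
                    ia, ib = self.tipsets[a.id], self.tipsets[b.id]
                    gi, gj = np.meshgrid(ia, ib, indexing="ij")
                    pi.append(gi.ravel())
                    pj.append(gj.ravel())
                    pm.append(np.full(gi.size, node.id))
        self.pair_i = np.concatenate(pi) if pi else np.empty(0, dtype=np.intp)
        self.pair_j = np.concatenate(pj) if pj else np.empty(0, dtype=np.intp)
        self.pair_mrca = np.concatenate(pm) if pm else np.empty(0, dtype=np.intp)

    def lineage_pass(
        self,
        alpha_by_state: np.ndarray,
        sigma2_by_state: np.ndarray,
        r: float,
        root_V: float,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Root-to-tip recursion.  Returns per-node arrays indexed by node id:
        decay[v] = e^{-A(0, t_v)}, logdecay[v] = -A(0, t_v), V[v], omega[v, k].
        logdecay is kept separately so covariances stay finite at extreme
        pull strengths where the linear decay underflows."""
        tree = self.tree
        nn = len(tree.nodes)
        ns = len(self.states)
        decay = [1.0] * nn
        logdecay = [0.0] * nn
        V = [0.0] * nn
        omega = np.zeros((nn, ns))
        V[tree.root.id] = root_V
        exp = math.exp
        for node in tree.preorder():
            if node is tree.root:
                continue
            p = node.parent.id
            segs = self.segments[node.id]
            m = len(segs)
            if m == 1:
                a, b, k = segs[0]
                al = alpha_by_state[k]
                branch_decay = exp(-al * (b - a))
                branch_A = al * (b - a)
                v = V[p] * branch_decay * branch_decay + _seg_var_integral(
                    sigma2_by_state[k], al, r, a, b)
                w = omega[p] * branch_decay
                w[k] += 1.0 - branch_decay
            else:
                seg_decay = [exp(-alpha_by_state[k] * (b - a)) for a, b, k in segs]
                branch_A = sum(alpha_by_state[k] * (b - a) for a, b, k in segs)
                # suffix[i] = product of decays of segments after i
                suffix = [1.0] * m
                for i in range(m - 2, -1, -1):
                    suffix[i] = suffix[i + 1] * seg_decay[i + 1]
                branch_decay = suffix[0] * seg_decay[0]
                v = V[p] * branch_decay * branch_decay
                w = omega[p] * branch_decay
                for i, (a, b, k) in enumerate(segs):
                    v += suffix[i] ** 2 * _seg_var_integral(
                        sigma2_by_state[k], alpha_by_state[k], r, a, b
                    )
                    w[k] += suffix[i] * (1.0 - seg_decay[i])
            decay[node.id] = decay[p] * branch_decay
            logdecay[node.id] = logdecay[p] - branch_A
            V[node.id] = v
            omega[node.id] = w
        return np.array(decay), np.array(logdecay), np.array(V), omega

    def tip_cov(self, logdecay: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Tip covariance: each (i, j) pair is filled once, at its MRCA, as
        V[mrca] * exp(logdecay_i - logdecay_mrca) * exp(logdecay_j - ...)."""
        n = self.tree.n_tips
        ldt = logdecay[self.tip_ids]
        vals = V[self.pair_mrca] * np.exp(
            ldt[self.pair_i] + ldt[self.pair_j] - 2.0 * logdecay[self.pair_mrca]
        )
        C = np.zeros((n, n))
        C[self.pair_i, self.pair_j] = vals
        C[self.pair_j, self.pair_i] = vals
        C[np.arange(n), np.arange(n)] = V[self.tip_ids]
        return C

    def tip_arrays(self, decay, V, omega):
        ids = [t.id for t in self.tree.tips]
        return decay[ids], V[ids], omega[ids]


def _state_vectors(
    cache: _Cache, config: ModelConfig, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Resolve per-state (alpha, sigma2) arrays and the burst exponent."""
    ns = len(cache.states)
    alpha = np.zeros(ns)
    sigma2 = np.empty(ns)
    for i, s in enumerate(cache.states):
        sigma2[i] = params.sigma2_for(s)
    r = 0.0
    mc = config.model_class
    if mc == "OU":
        alpha[:] = params.alpha
    elif mc == "ER":
        alpha[cache.state_index["pre"]] = params.alpha
    elif mc == "EB":
        r = params.r
    return alpha, sigma2, r


def trait_moments(
    tree: PhyloTree,
    config: ModelConfig,
    params: ModelParams,
    root_mode: str = "fixed",
) -> GaussianMoments:
    """Exact tip mean vector and covariance matrix for a scenario."""
    if root_mode not in ("fixed", "stationary"):
        raise ValueError(f"unknown root_mode {root_mode!r}")
    cache = _Cache(tree, config)
    alpha, sigma2, r = _state_vectors(cache, config, params)
    root_alpha = alpha[cache.state_index[cache.root_state]]
    root_V = 0.0
    if root_mode == "stationary":
        if root_alpha <= 0:
            raise ValueError("stationary root requires alpha > 0 in the root regime")
        root_V = sigma2[cache.state_index[cache.root_state]] / (2.0 * root_alpha)
    decay_n, logdecay_n, V_n, omega_n = cache.lineage_pass(alpha, sigma2, r, root_V)
    decay, V, omega = cache.tip_arrays(decay_n, V_n, omega_n)

    has_pull = bool(np.any(alpha > 0))
    if root_mode == "stationary":
        x0 = params.theta_for(cache.root_state)
    elif params.x0 is not None:
        x0 = params.x0
    elif has_pull:
        x0 = params.theta_for(cache.root_state)
    else:
        raise ValueError("x0 required for models without pull")
    mean = x0 * decay
    if has_pull:
        for i, s in enumerate(cache.states):
            if alpha[i] > 0:
                mean = mean + params.theta_for(s) * omega[:, i]
    cov = cache.tip_cov(logdecay_n, V_n)
    return GaussianMoments(list(tree.taxa), mean, cov)


# -- likelihood --------------------------------------------------------


def _chol(cov: np.ndarray):
    jitter = _JITTER * np.trace(cov) / cov.shape[0]
    try:
        return cho_factor(cov + jitter * np.eye(cov.shape[0]), lower=True)
    except LinAlgError:
        raise LinAlgError("covariance singular beyond jitter tolerance") from None


def loglik(moments: GaussianMoments, traits: Mapping[str, float]) -> float:
    """Multivariate-normal log density of a tip trait vector."""
    y = np.array([traits[t] for t in moments.taxa], dtype=float)
    n = len(y)
    cf = _chol(moments.cov)
    resid = y - moments.mean
    quad = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


# -- ML fitting --------------------------------------------------------


def _profiled_nll(cache: _Cache, y: np.ndarray, alpha, sigma2rel, r, root_mode):
    """GLS-profile the mean parameters and the global rate scale.

    Returns (nll, beta, sigma2_hat, mean_states) or None when the relative
    covariance cannot be factorized.
    """
    root_idx = cache.state_index[cache.root_state]
    root_V = 0.0
    if root_mode == "stationary":
        if alpha[root_idx] <= 0:
            return None
        root_V = sigma2rel[root_idx] / (2.0 * alpha[root_idx])
    decay_n, logdecay_n, V_n, omega_n = cache.lineage_pass(alpha, sigma2rel, r, root_V)
    decay, V, omega = cache.tip_arrays(decay_n, V_n, omega_n)
    Ct = cache.tip_cov(logdecay_n, V_n)

    theta_states = [s for s in cache.states if alpha[cache.state_index[s]] > 0]
    if theta_states:
        cols = []
        for s in theta_states:
            col = omega[:, cache.state_index[s]].copy()
            if s == cache.root_state:  # root value tied to the root-regime optimum
                col = col + decay
            cols.append(col)
        if cache.root_state not in theta_states:
            cols.append(decay)  # free root value when the root regime has no pull
            theta_states = theta_states + ["__x0__"]
        M = np.column_stack(cols)
    else:
        M = decay[:, None]
        theta_states = ["__x0__"]

    n = len(y)
    try:
        cf = _chol(Ct)
    except LinAlgError:
        return None
    Ci_M = cho_solve(cf, M)
    Ci_y = cho_solve(cf, y)
    A = M.T @ Ci_M
    b = M.T @ Ci_y
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = y - M @ beta
    quad = float(resid @ cho_solve(cf, resid))
    if quad <= 0:
        quad = 1e-300
    s2 = quad / n  # ML estimate of the global rate scale
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    nll = 0.5 * (n * math.log(2.0 * math.pi * s2) + logdet + n)
    return nll, beta, s2, theta_states


def _scenario_space(cache: _Cache, config: ModelConfig):
    """Describe the nonlinear search space: names + (lo, hi) bounds per axis."""
    T = cache.tree.root_height
    mc = config.model_class
    used = cache.used_states
    axes: list[tuple[str, float, float]] = []
    if mc == "OU":
        axes.append(("log_alpha", math.log(1e-9), math.log(2e3 / T)))
    elif mc == "EB":
        axes.append(("r", -10.0 / T, 0.0))
    elif mc == "ER":
        axes.append(("log_alpha", math.log(1e-9), math.log(2e3 / T)))
        if config.er_free_post_sigma:
            axes.append(("log_ratio:post", -22.0, 22.0))
    if mc in ("BM", "SHIFT") and len(used) > 1:
        for s in used[1:]:
            axes.append((f"log_ratio:{s}", -22.0, 22.0))
    return axes


def _apply_space(cache: _Cache, config: ModelConfig, axes, x):
    ns = len(cache.states)
    alpha = np.zeros(ns)
    sigma2rel = np.ones(ns)
    r = 0.0
    for (name, lo, hi), val in zip(axes, x):
        val = min(max(val, lo), hi)
        if name == "log_alpha":
            a = math.exp(val)
            if config.model_class == "ER":
                alpha[cache.state_index["pre"]] = a
            else:
                alpha[:] = a
        elif name == "r":
            r = val
        elif name.startswith("log_ratio:"):
            sigma2rel[cache.state_index[name.split(":", 1)[1]]] = math.exp(val)
    return alpha, sigma2rel, r


def _param_count(cache: _Cache, config: ModelConfig) -> int:
    mc = config.model_class
    n_used = len(cache.used_states)
    if mc == "BM":
        return 1 + n_used  # x0 + one rate per used regime
    if mc == "SHIFT":
        return 1 + n_used
    if mc == "EB":
        return 3  # x0, sigma0^2, r
    if mc == "OU":
        return 2 + n_used  # alpha, sigma^2, one optimum per used regime
    if mc == "ER":
        return (4 if config.er_free_post_sigma else 3) if n_used > 1 else 3
    raise AssertionError(mc)


def fit_model(
    tree: PhyloTree,
    config: ModelConfig,
    traits: Mapping[str, float],
    root_mode: str = "fixed",
    n_restarts: int = 5,
    _cache: _Cache | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one scenario to one trait vector."""
    cache = _cache if _cache is not None else _Cache(tree, config)
    y = np.array([traits[t] for t in tree.taxa], dtype=float)
    n = len(y)
    k = _param_count(cache, config)
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} tips with data, have {n}")

    axes = _scenario_space(cache, config)

    def objective(x: np.ndarray) -> float:
        alpha, sigma2rel, r = _apply_space(cache, config, axes, x)
        out = _profiled_nll(cache, y, alpha, sigma2rel, r, root_mode)
        return math.inf if out is None else out[0]

    converged = True
    restarts = 0
    if not axes:
        x_best = np.empty(0)
    elif len(axes) == 1:
        # coarse grid to bracket the optimum, then Brent inside the bracket
        name, lo, hi = axes[0]
        grid = np.linspace(lo, hi, 13)
        vals = np.array([objective(np.array([g])) for g in grid])
        i = int(np.argmin(vals))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda v: objective(np.array([v])),
            bounds=(blo, bhi), method="bounded", options={"xatol": 1e-8},
        )
        restarts += 1
        best_val, x_best = res.fun, np.array([res.x])
        if vals[i] < best_val:
            best_val, x_best = vals[i], np.array([grid[i]])
        # snap to the boundary when it is at least as good (e.g. r -> 0)
        for edge in (lo, hi):
            edge_val = objective(np.array([edge]))
            if edge_val <= best_val + 1e-9:
                x_best, best_val = np.array([edge]), edge_val
                break
    else:
        rng = np.random.default_rng(0)
        los = np.array([a[1] for a in axes])
        his = np.array([a[2] for a in axes])
        mid = 0.5 * (los + his)
        starts = [np.zeros(len(axes)), mid] + [
            rng.uniform(np.maximum(los, -8), np.minimum(his, 8))
            for _ in range(max(n_restarts - 2, 1))
        ]
        best_val, x_best, converged = math.inf, mid, False
        for x0 in starts:
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 800})
            restarts += 1
            if res.fun < best_val:
                best_val, x_best, converged = res.fun, res.x, bool(res.success)

    alpha, sigma2rel, r = _apply_space(cache, config, axes, x_best)
    out = _profiled_nll(cache, y, alpha, sigma2rel, r, root_mode)
    if out is None:
        raise LinAlgError(f"covariance singular for {config.scenario_name}")
    nll, beta, s2, theta_states = out

    sigma2_map = {s: s2 * sigma2rel[cache.state_index[s]] for s in cache.states}
    params = ModelParams(
        sigma2=sigma2_map if len(cache.used_states) > 1 else s2,
        alpha=float(alpha.max()),
        r=r,
    )
    thetas = {s: float(b) for s, b in zip(theta_states, beta) if s != "__x0__"}
    if "__x0__" in theta_states:
        params.x0 = float(beta[theta_states.index("__x0__")])
    if thetas:
        params.theta = thetas if len(thetas) > 1 else next(iter(thetas.values()))
        if root_mode == "fixed" and params.x0 is None:
            params.x0 = params.theta_for(cache.root_state) if isinstance(
                params.theta, Mapping) else float(params.theta)
    ll = -nll
    return FitResult(
        config=config, params=params, loglik=ll, k=k, n=n,
        aicc=aicc(ll, k, n), converged=converged, n_restarts=restarts,
    )


# -- the 11-scenario suite ---------------------------------------------


def build_scenarios(
    tree: PhyloTree,
    habitat_painting: RegimePainting,
    clade_painting: RegimePainting,
    geo_painting: RegimePainting,
    slice_age: float = 2.6,
    er_free_post_sigma: bool = False,
) -> list[ModelConfig]:
    """The 11 named configurations, in fixed comparison-table order."""
    for name, painting, expected in [
        ("habitat", habitat_painting, 2),
        ("clade", clade_painting, 2),
        ("geo", geo_painting, 3),
    ]:
        if len(painting.states) not in (1, expected):
            raise ValueError(
                f"{name} painting must have {expected} states (or 1 for the "
                f"degenerate case), got {len(painting.states)}"
            )
    return [
        ModelConfig("BM", "BM1"),
        ModelConfig("EB", "EB"),
        ModelConfig("OU", "OU1"),
        ModelConfig("SHIFT", "SHIFT", slice_age=slice_age),
        ModelConfig("ER", "ER", slice_age=slice_age, er_free_post_sigma=er_free_post_sigma),
        ModelConfig("BM", "BMM_Regime", painting=habitat_painting),
        ModelConfig("OU", "OUM_Regime", painting=habitat_painting),
        ModelConfig("BM", "BMM_Clade", painting=clade_painting),
        ModelConfig("OU", "OUM_Clade", painting=clade_painting),
        ModelConfig("BM", "BMM_Geo", painting=geo_painting),
        ModelConfig("OU", "OUM_Geo", painting=geo_painting),
    ]


@dataclass
class ComparisonTable:
    scenarios: list[str]
    reference_delta: np.ndarray
    quantiles: np.ndarray | None  # (n_scenarios, 3): 10/50/90%
    reference_fits: list[FitResult]
    n_sample_trees: int = 0
    n_failed: int = 0

    def best_scenario(self) -> str:
        return self.scenarios[int(np.argmin(self.reference_delta))]

    def to_frame(self):
        import pandas as pd

        rows = {}
        for i, s in enumerate(self.scenarios):
            cell = f"{self.reference_delta[i]:.2f}"
            if self.quantiles is not None:
                q = self.quantiles[i]
                cell += f"({q[0]:.2f};{q[1]:.2f};{q[2]:.2f})"
            rows[s] = cell
        return pd.DataFrame({"dAICc": rows})


def compare_scenarios(
    trees: Sequence[PhyloTree],
    traits: Mapping[str, float],
    scenario_builder: Callable[[PhyloTree], list[ModelConfig]],
    root_mode: str = "fixed",
) -> ComparisonTable:
    """Fit the scenario suite on a reference tree and a posterior sample.

    ``trees[0]`` is the reference; paintings are rebuilt per tree by
    ``scenario_builder``.  Failures on sample trees are dropped from the
    quantiles; a failure on the reference raises.
    """
    ref = trees[0]
    configs = scenario_builder(ref)
    names = [c.scenario_name for c in configs]
    ref_fits = [fit_model(ref, c, traits, root_mode=root_mode) for c in configs]
    ref_aicc = np.array([f.aicc for f in ref_fits])
    ref_delta = ref_aicc - ref_aicc.min()

    deltas = []
    n_failed = 0
    for tree in trees[1:]:
        try:
            cfgs = scenario_builder(tree)
            aiccs = np.array(
                [fit_model(tree, c, traits, root_mode=root_mode).aicc for c in cfgs]
            )
            deltas.append(aiccs - aiccs.min())
        except (ValueError, LinAlgError):
            n_failed += 1
    quants = None
    if deltas:
        arr = np.vstack(deltas)
        quants = np.quantile(arr, [0.10, 0.50, 0.90], axis=0).T
    return ComparisonTable(
        scenarios=names,
        reference_delta=ref_delta,
        quantiles=quants,
        reference_fits=ref_fits,
        n_sample_trees=len(deltas),
        n_failed=n_failed,
    )
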