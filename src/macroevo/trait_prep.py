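"""Data preparation: log range-midpoints, phylogenetic-eigenvector-augmented
imputation, independent contrasts, GLS size correction, phylogenetic PCA."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .trees import Node, PhyloTree, parse_newick, shared_time_matrix, write_newick

__all__ = [
    "PPCAResult",
    "ImputationResult",
    "log_midpoint_means",
    "pvr_eigenvectors",
    "iterative_impute",
    "pic",
    "pic_correlation",
    "gls_residuals",
    "phylo_pca",
]

log = logging.getLogger(__name__)


def log_midpoint_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait species means as (log min + log max) / 2.

    Expects ``<trait>_min`` / ``<trait>_max`` column pairs; missing cells
    propagate, nonpositive values raise.
    """
    traits = sorted({c[:-4] for c in table.columns if c.endswith("_min")})
    for t in traits:
        if f"{t}_max" not in table.columns:
            raise ValueError(f"column {t}_max missing")
    values = table[[c for c in table.columns if c.endswith(("_min", "_max"))]]
    if (values <= 0).any().any():
        raise ValueError("range values must be positive (log scale)")
    both = {
        t: (table[f"{t}_min"] > table[f"{t}_max"])
        for t in traits
    }
    for t, bad in both.items():
        if bad.any():
            raise ValueError(f"min > max for trait {t!r}: {list(table.index[bad])}")
    out = {}
    for t in traits:
        out[t] = 0.5 * (np.log(table[f"{t}_min"]) + np.log(table[f"{t}_max"]))
    return pd.DataFrame(out, index=table.index)


def pvr_eigenvectors(tree: PhyloTree, k: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of the patristic distance matrix.

    Gower double-centering of -0.5 D^2, eigenvectors ordered by eigenvalue;
    variance fractions are taken over the positive eigenvalues only.
    """
    n = tree.n_tips
    if k > n - 1:
        raise ValueError(f"k={k} too large for {n} tips (max {n - 1})")
    C = shared_time_matrix(tree).matrix
    depths = np.diag(C)
    D = depths[:, None] + depths[None, :] - 2.0 * C
    G = -0.5 * D * D
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ G @ J
    G = 0.5 * (G + G.T)
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > 1e-10 * max(w.max(), 1.0)
    fractions = np.where(pos, w, 0.0) / w[pos].sum()
    cols = [f"PVR{i + 1}" for i in range(k)]
    return pd.DataFrame(V[:, :k], index=tree.taxa, columns=cols), fractions[:k]


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    nrmse: float
    n_iter: int
    eigenvectors_used: int
    seed: int


class _RidgeImputer:
    """Deterministic ridge fallback; NRMSE from leave-one-out residuals.

    Predictors are standardized before the penalty is applied so one lambda
    works across traits and eigenvector columns alike.
    """

    def __init__(self, lam: float = 0.1):
        self.lam = lam

    def fit_predict(self, Xtr, ytr, Xmis, rng):
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Z = np.column_stack([np.ones(len(Xtr)), (Xtr - mu) / sd])
        A = Z.T @ Z + self.lam * len(Z) * np.eye(Z.shape[1])
        beta = np.linalg.solve(A, Z.T @ ytr)
        fitted = Z @ beta
        H = Z @ np.linalg.solve(A, Z.T)
        h = np.clip(np.diag(H), 0.0, 1.0 - 1e-8)
        loo = (ytr - fitted) / (1.0 - h)
        if len(Xmis):
            Zm = np.column_stack([np.ones(len(Xmis)), (Xmis - mu) / sd])
            pred = Zm @ beta
        else:
            pred = np.empty(0)
        return pred, loo


class _ForestImputer:
    """Random-forest ensemble; NRMSE from out-of-bag predictions."""

    def __init__(self, ntree: int = 100):
        self.ntree = ntree

    def fit_predict(self, Xtr, ytr, Xmis, rng):
        from sklearn.ensemble import RandomForestRegressor

        rf = RandomForestRegressor(
            n_estimators=self.ntree,
            oob_score=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(Xtr, ytr)
            oob = rf.oob_prediction_
        heldout = ytr - oob
        pred = rf.predict(Xmis) if len(Xmis) else np.empty(0)
        return pred, heldout


def iterative_impute(
    data: pd.DataFrame,
    eigvecs: pd.DataFrame | None = None,
    maxiter: int = 20,
    regressor: str = "forest",
    ntree: int = 100,
    ridge_lambda: float = 0.1,
    seed: int = 0,
) -> ImputationResult:
    """Iterative chained imputation over a trait matrix, optionally augmented
    with fully observed phylogenetic eigenvector columns (never imputed).

    Columns are processed in increasing-missingness order, missing cells start
    at column means, and the sweep stops at the first increase of the summed
    squared change (the previous sweep's values are kept) or at ``maxiter``.
    """
    X = data.copy().astype(float)
    if X.isna().all(axis=0).any():
        bad = list(X.columns[X.isna().all(axis=0)])
        raise ValueError(f"fully missing columns: {bad}")
    if X.isna().all(axis=1).any():
        bad = list(X.index[X.isna().all(axis=1)])
        raise ValueError(f"fully missing rows: {bad}")
    n_eig = 0
    if eigvecs is not None:
        eig = eigvecs.loc[X.index]
        if eig.isna().any().any():
            raise ValueError("eigenvector columns must be fully observed")
        n_eig = eig.shape[1]

    rng = np.random.default_rng(seed)
    imp = {"forest": _ForestImputer(ntree),
           "ridge": _RidgeImputer(ridge_lambda)}[regressor]
    miss_mask = X.isna()
    incomplete = [c for c in X.columns if miss_mask[c].any()]
    if not incomplete:
        return ImputationResult(X, 0.0, 0, n_eig, seed)
    incomplete.sort(key=lambda c: miss_mask[c].sum())

    filled = X.fillna(X.mean())
    prev = filled.copy()
    prev_change = math.inf
    heldout_sq: dict[str, float] = {}
    obs_var: dict[str, float] = {}
    n_iter = 0
    for it in range(1, maxiter + 1):
        current = prev.copy()
        for col in incomplete:
            obs = ~miss_mask[col]
            others = [c for c in X.columns if c != col]
            design = current[others]
            if n_eig:
                design = pd.concat([design, eig], axis=1)
            Xtr = design[obs].to_numpy()
            ytr = X.loc[obs, col].to_numpy()
            Xmis = design[~obs].to_numpy()
            pred, heldout = imp.fit_predict(Xtr, ytr, Xmis, rng)
            # never extrapolate beyond the observed range (forest-like bound)
            current.loc[~obs, col] = np.clip(pred, ytr.min(), ytr.max())
            heldout_sq[col] = float(np.sum(heldout**2)) / len(ytr)
            obs_var[col] = float(np.var(ytr))
        diff = (current - prev).to_numpy()
        denom = float(np.sum(current.to_numpy() ** 2))
        change = float(np.sum(diff**2)) / denom if denom > 0 else 0.0
        n_iter = it
        if change > prev_change:
            current = prev  # revert to the previous sweep
            break
        prev = current
        prev_change = change
        if change == 0.0:
            break
    num = np.mean([heldout_sq[c] for c in incomplete])
    den = np.mean([obs_var[c] for c in incomplete])
    nrmse = math.sqrt(num / den) if den > 0 else 0.0
    completed = prev
    # observed cells are contractually untouched
    assert ((completed == X) | miss_mask).all().all()
    return ImputationResult(completed, nrmse, n_iter, n_eig, seed)


# -- contrasts and GLS -------------------------------------------------


def _resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    t = parse_newick(write_newick(tree))
    changed = False
    for node in list(t.preorder()):
        while len(node.children) > 2:
            changed = True
            a = node.children.pop(0)
            b = node.children.pop(0)
            merged = Node(length=0.0)
            merged.children = [a, b]
            a.parent = b.parent = merged
            merged.parent = node
            node.children.insert(0, merged)
    if changed:
        log.info("polytomies resolved arbitrarily with zero-length branches")
        return PhyloTree(t.root)
    return tree


def pic(tree: PhyloTree, x) -> np.ndarray:
    """Standardized independent contrasts (n-1 values, postorder)."""
    vals = {t: float(x[t]) for t in tree.taxa}
    if any(v != v for v in vals.values()):
        raise ValueError("missing trait values")
    tree = _resolve_polytomies(tree)
    node_val: dict[int, float] = {}
    adj_len: dict[int, float] = {}
    contrasts = []
    for node in tree.postorder():
        if node.is_tip:
            node_val[node.id] = vals[node.label]
            adj_len[node.id] = node.length or 0.0
            continue
        (a, b) = node.children
        la, lb = adj_len[a.id], adj_len[b.id]
        xa, xb = node_val[a.id], node_val[b.id]
        contrasts.append((xa - xb) / math.sqrt(la + lb))
        node_val[node.id] = (xa / la + xb / lb) / (1 / la + 1 / lb) if la > 0 and lb > 0 \
            else 0.5 * (xa + xb)
        extra = la * lb / (la + lb) if la + lb > 0 else 0.0
        adj_len[node.id] = (node.length or 0.0) + extra
    return np.array(contrasts)


def pic_correlation(tree: PhyloTree, x, y) -> tuple[float, float]:
    """Correlation of contrasts through the origin with a t-test p-value."""
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    u = pic(tree, x)
    v = pic(tree, y)
    denom = math.sqrt(float(u @ u) * float(v @ v))
    if denom == 0:
        raise ValueError("zero-variance contrasts")
    r = float(u @ v) / denom
    df = len(u) - 1  # regression through the origin on n-1 contrasts
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, p


def _gls_chol(tree: PhyloTree):
    C = shared_time_matrix(tree).matrix
    n = C.shape[0]
    return cho_factor(C + 1e-12 * np.trace(C) / n * np.eye(n), lower=True)


def gls_residuals(tree: PhyloTree, y, x) -> pd.Series:
    """Residuals of the phylogenetic regression y ~ x (tree-structured GLS)."""
    yv = np.array([float(y[t]) for t in tree.taxa])
    xv = np.array([float(x[t]) for t in tree.taxa])
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones_like(xv), xv])
    cf = _gls_chol(tree)
    CiX = cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ CiX, X.T @ cho_solve(cf, yv))
    return pd.Series(yv - X @ beta, index=tree.taxa)


# -- phylogenetic PCA --------------------------------------------------


@dataclass
class PPCAResult:
    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    mode: str
    phylo_means: pd.Series

    def loadings_table(self, n_axes: int = 2) -> pd.DataFrame:
        cols = self.loadings.columns[:n_axes]
        table = self.loadings[cols].copy()
        table.loc["Eigenvalue"] = self.eigenvalues[:n_axes]
        table.loc["Proportion of Variance"] = self.proportion[:n_axes]
        table.loc["Cumulative proportion"] = self.cumulative[:n_axes]
        return table


def phylo_pca(tree: PhyloTree, X: pd.DataFrame, mode: str = "cov") -> PPCAResult:
    """PCA of the evolutionary (GLS-weighted) covariance of tip traits.

    Loadings are evolutionary correlations between traits and scores; each
    axis is flipped so its largest-magnitude loading is negative (a cosmetic
    sign convention for table comparison).
    """
    if mode not in ("cov", "cor"):
        raise ValueError(f"unknown mode {mode!r}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    if X.isna().any().any():
        raise ValueError("matrix must be complete")
    Xv = X.loc[tree.taxa].to_numpy(dtype=float)
    n, p = Xv.shape
    cf = _gls_chol(tree)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    a = (Xv.T @ Ci1) / float(ones @ Ci1)
    Xc = Xv - a[None, :]
    R = Xc.T @ cho_solve(cf, Xc) / (n - 1)
    R = 0.5 * (R + R.T)
    if mode == "cor":
        sd = np.sqrt(np.diag(R))
        Xc = Xc / sd[None, :]
        R = R / np.outer(sd, sd)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    loadings = V * np.sqrt(w)[None, :] / np.sqrt(np.diag(R))[:, None]
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] > 0:
            loadings[:, k] *= -1.0
            V[:, k] *= -1.0
    scores = Xc @ V
    axes = [f"pPC{i + 1}" for i in range(p)]
    total = w.sum()
    prop = w / total if total > 0 else w
    return PPCAResult(
        eigenvalues=w,
        proportion=prop,
        cumulative=np.cumsum(prop),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=axes),
        scores=pd.DataFrame(scores, index=tree.taxa, columns=axes),
        mode=mode,
        phylo_means=pd.Series(a, index=X.columns),
    )
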