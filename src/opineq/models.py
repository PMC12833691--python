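"""Environment-only health determination models: OLS, conditional inference tree,
random forest.

All three families regress the continuous transformed health variable on the
circumstance covariates only; their fitted values form the counterfactual
"smoothed" distribution whose inequality is the absolute opportunity
inequality.

The conditional inference tree follows the permutation-test recursive
partitioning scheme: at every node a global independence test is run for each
candidate covariate against the response, p-values are Bonferroni-adjusted
across candidates, and splitting stops when the smallest adjusted p-value
fails the significance level.  The selected covariate is split at the point
maximising the standardized two-sample statistic between the child samples.
This selection-by-significance avoids the variable-selection bias of
impurity-based trees.  The association test defaults to the exact
t-distribution p-value of the Pearson statistic (equivalent rank ordering to
the standardized linear statistic); a Monte-Carlo permutation version is
available via ``test_method="permutation"``.

The random forest is a standard bagged regression forest (scikit-learn
backend): B bootstrap resamples, m random candidate covariates per split,
prediction = the average of the per-tree predictions, with out-of-bag error
computed from the trees whose resample excluded each observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split

__all__ = [
    "FittedHealthModel",
    "CitNode",
    "fit_linear",
    "cit_test",
    "fit_cit",
    "fit_forest",
    "tune_depth",
    "evaluate",
    "stratified_split",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def _as_vector(y) -> np.ndarray:
    if hasattr(y, "values") and not isinstance(y, (pd.Series, pd.DataFrame)):
        y = y.values  # HealthVector
    return np.asarray(y, dtype=float).ravel()


@dataclass
class FittedHealthModel:
    """A fitted environment-only predictor of health."""

    family: str  # linear | cit | forest
    fitted: np.ndarray
    columns: list[str]
    hyperparams: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    coef_: np.ndarray | None = None  # linear only (intercept first)
    root: "CitNode | None" = None  # cit only
    sk_model: RandomForestRegressor | None = None  # forest only

    def predict(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        if self.family == "linear":
            return self.coef_[0] + M @ self.coef_[1:]
        if self.family == "cit":
            return _cit_predict(self.root, M)
        return self.sk_model.predict(M)


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------

def fit_linear(X, y) -> FittedHealthModel:
    """Ordinary least squares with intercept; errors name collinear columns."""
    M, cols = _as_matrix(X)
    yv = _as_vector(y)
    n, k = M.shape
    if n <= k:
        raise ValueError(f"need n > k (got n={n}, k={k})")
    D = np.column_stack([np.ones(n), M])
    _, R, piv = sla.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < k + 1:
        bad = sorted(piv[rank:])
        names = ["intercept" if j == 0 else cols[j - 1] for j in bad]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")
    beta, *_ = np.linalg.lstsq(D, yv, rcond=None)
    fitted = D @ beta
    return FittedHealthModel(family="linear", fitted=fitted, columns=cols,
                             coef_=beta, hyperparams={},
                             diagnostics=_insample_diag(yv, fitted))


def _insample_diag(y, fitted) -> dict:
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    return {"train_mse": float(np.mean(resid ** 2)),
            "train_r2": float(1.0 - np.sum(resid ** 2) / sst) if sst > 0 else float("nan")}


# ---------------------------------------------------------------------------
# conditional inference tree
# ---------------------------------------------------------------------------

def cit_test(x, y, *, method: str = "asymptotic", n_perm: int = 9999,
             rng: np.random.Generator | None = None) -> float:
    """P-value of the independence null between one covariate and the response.

    ``asymptotic``: exact t-distribution p-value of the Pearson statistic.
    ``permutation``: Monte-Carlo permutation of the absolute correlation with
    the add-one estimator ``(1 + #{|r*| >= |r|}) / (n_perm + 1)``.
    Zero-variance inputs give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    if method == "asymptotic":
        if abs(r) >= 1.0:
            return 0.0
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if method == "permutation":
        rng = np.random.default_rng(rng)
        hits = 0
        for _ in range(n_perm):
            rp = xc @ rng.permutation(yc) / denom
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        return (1.0 + hits) / (n_perm + 1.0)
    raise ValueError(f"unknown test method {method!r}")


@dataclass
class CitNode:
    """A node of the conditional inference tree."""

    n: int
    value: float
    feature: int = -1  # -1 for leaf
    threshold: float = float("nan")
    p_adj: float = float("nan")
    left: "CitNode | None" = None
    right: "CitNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


def _best_split(xs: np.ndarray, ys: np.ndarray, min_leaf: int):
    """Best split point of a sorted covariate by the standardized two-sample
    statistic; returns (threshold, statistic) or None.  Ties -> smallest c."""
    n = len(xs)
    if n < 2 * min_leaf:
        return None
    syy = float(np.sum((ys - ys.mean()) ** 2))
    if syy == 0:
        return None
    nl = np.arange(1, n)
    cum = np.cumsum(ys)[:-1]
    var = nl * (n - nl) / (n * (n - 1.0)) * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(cum - nl * ys.mean()) / np.sqrt(var)
    valid = (xs[:-1] < xs[1:]) & (nl >= min_leaf) & (n - nl >= min_leaf)
    if not valid.any():
        return None
    z = np.where(valid, z, -np.inf)
    i = int(np.argmax(z))  # first maximum -> smallest threshold
    return (xs[i] + xs[i + 1]) / 2.0, float(z[i])


def fit_cit(X, y, *, alpha: float = 0.05, max_depth: int | None = None,
            min_node: int = 20, min_leaf: int = 7,
            test_method: str = "asymptotic", n_perm: int = 9999,
            seed: int | None = None) -> FittedHealthModel:
    """Fit a conditional inference tree.

    A node becomes a leaf when the Bonferroni-adjusted global test is not
    rejected at ``alpha``, the depth limit is reached, or fewer than
    ``min_node`` observations remain; children must have at least ``min_leaf``
    observations.  Predictions are leaf means.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if max_depth is not None and max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    M, cols = _as_matrix(X)
    yv = _as_vector(y)
    n, k = M.shape
    rng = np.random.default_rng(seed)
    # presorted row indices per covariate, filtered down the recursion
    orders = [np.argsort(M[:, j], kind="stable") for j in range(k)]

    def grow(idx: np.ndarray, orders_node: list[np.ndarray], depth: int) -> CitNode:
        node = CitNode(n=len(idx), value=float(yv[idx].mean()))
        if (max_depth is not None and depth >= max_depth) or len(idx) < min_node:
            return node
        pvals = np.array([cit_test(M[idx, j], yv[idx], method=test_method,
                                   n_perm=n_perm, rng=rng) for j in range(k)])
        n_tested = int((pvals < 1.0).sum()) or 1
        p_adj = np.minimum(1.0, pvals * n_tested)
        j_star = int(np.argmin(p_adj))
        if p_adj[j_star] >= alpha:
            return node
        o = orders_node[j_star]
        split = _best_split(M[o, j_star], yv[o], min_leaf)
        if split is None:
            return node
        c, _ = split
        node.feature, node.threshold, node.p_adj = j_star, float(c), float(p_adj[j_star])
        go_left = M[:, j_star] <= c
        left_orders = [o2[go_left[o2]] for o2 in orders_node]
        right_orders = [o2[~go_left[o2]] for o2 in orders_node]
        node.left = grow(left_orders[0], left_orders, depth + 1)
        node.right = grow(right_orders[0], right_orders, depth + 1)
        return node

    root = grow(orders[0], orders, 0)
    fitted = _cit_predict(root, M)
    return FittedHealthModel(
        family="cit", fitted=fitted, columns=cols, root=root,
        hyperparams={"alpha": alpha, "max_depth": max_depth, "min_node": min_node,
                     "min_leaf": min_leaf, "test_method": test_method},
        diagnostics=_insample_diag(yv, fitted))


def _cit_predict(node: CitNode, M: np.ndarray) -> np.ndarray:
    out = np.empty(len(M))

    def walk(nd: CitNode, mask: np.ndarray):
        if nd.is_leaf:
            out[mask] = nd.value
            return
        left = mask & (M[:, nd.feature] <= nd.threshold)
        walk(nd.left, left)
        walk(nd.right, mask & ~left)

    walk(node, np.ones(len(M), dtype=bool))
    return out


def cit_to_arrays(root: CitNode) -> dict:
    """Flatten a conditional inference tree to the array form shared with
    scikit-learn trees (children, feature, threshold, leaf value, cover)."""
    feat, thr, left, right, value, cover = [], [], [], [], [], []

    def add(nd: CitNode) -> int:
        i = len(feat)
        feat.append(nd.feature)
        thr.append(nd.threshold)
        value.append(nd.value)
        cover.append(float(nd.n))
        left.append(-1)
        right.append(-1)
        if not nd.is_leaf:
            left[i] = add(nd.left)
            right[i] = add(nd.right)
        return i

    add(root)
    return {"children_left": np.array(left), "children_right": np.array(right),
            "feature": np.array(feat), "threshold": np.array(thr),
            "value": np.array(value), "cover": np.array(cover)}


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def fit_forest(X, y, *, n_trees: int = 500, max_features: int | None = None,
               max_depth: int | None = None, min_leaf: int = 5,
               bootstrap: bool = True, seed: int | None = None) -> FittedHealthModel:
    """Bagged regression forest; prediction = mean of the per-tree predictions.

    ``max_features`` defaults to ``max(1, k // 3)``.  Out-of-bag predictions
    are the mean over trees whose bootstrap resample excluded the observation;
    rows that are never out of bag (tiny forests) are excluded from the OOB
    error with a warning.
    """
    M, cols = _as_matrix(X)
    yv = _as_vector(y)
    n, k = M.shape
    m = max_features if max_features is not None else max(1, k // 3)
    if not 1 <= m <= k:
        raise ValueError(f"max_features must lie in [1, {k}]")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=m, max_depth=max_depth,
        min_samples_leaf=min_leaf, bootstrap=bootstrap,
        random_state=None if seed is None else int(seed) % (2 ** 31),
        n_jobs=1)
    rf.fit(M, yv)
    fitted = rf.predict(M)
    diag = _insample_diag(yv, fitted)
    if bootstrap:
        diag.update(_oob_error(rf, M, yv))
    return FittedHealthModel(
        family="forest", fitted=fitted, columns=cols, sk_model=rf,
        hyperparams={"n_trees": n_trees, "max_features": m, "max_depth": max_depth,
                     "min_leaf": min_leaf, "bootstrap": bootstrap, "seed": seed},
        diagnostics=diag)


def _oob_error(rf: RandomForestRegressor, M: np.ndarray, y: np.ndarray) -> dict:
    n = len(y)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for est, sampled in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        if oob.any():
            sums[oob] += est.predict(M[oob])
            counts[oob] += 1
    covered = counts > 0
    if not covered.all():
        warnings.warn(f"{int((~covered).sum())} observation(s) never out of bag; "
                      "excluded from the OOB error", stacklevel=3)
    if not covered.any():
        return {"oob_error": float("nan"), "oob_n": 0}
    oob_pred = sums[covered] / counts[covered]
    return {"oob_error": float(np.mean((oob_pred - y[covered]) ** 2)),
            "oob_n": int(covered.sum())}


# ---------------------------------------------------------------------------
# tuning and evaluation
# ---------------------------------------------------------------------------

_FITTERS = {"linear": fit_linear, "cit": fit_cit, "forest": fit_forest}


def fit_family(family: str, X, y, **kw) -> FittedHealthModel:
    """Dispatch to a model family's fitter."""
    try:
        return _FITTERS[family](X, y, **kw)
    except KeyError:
        raise ValueError(f"unknown model family {family!r}") from None


def tune_depth(family: str, X, y, *, grid=None, folds: int = 5,
               seed: int | None = None, **fit_kw) -> int:
    """Depth maximising mean cross-validated negative MSE; ties -> smallest depth."""
    if family not in ("cit", "forest"):
        raise ValueError("depth tuning applies to tree families only")
    grid = sorted(grid) if grid is not None else list(range(1, 21))
    if not grid:
        raise ValueError("grid must be nonempty")
    M, _ = _as_matrix(X)
    yv = _as_vector(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=None if seed is None
               else int(seed) % (2 ** 31))
    splits = list(kf.split(M))
    best_depth, best_score = None, np.inf
    for depth in grid:
        mses = []
        for tr, va in splits:
            model = fit_family(family, M[tr], yv[tr], max_depth=depth,
                               seed=seed, **fit_kw)
            mses.append(float(np.mean((model.predict(M[va]) - yv[va]) ** 2)))
        score = float(np.mean(mses))
        if score < best_score - 1e-12:
            best_depth, best_score = depth, score
    return best_depth


def evaluate(model: FittedHealthModel, X_test, y_test) -> dict:
    """Test-set MSE and R-squared (R2 is NaN with a warning for constant y)."""
    yv = _as_vector(y_test)
    pred = model.predict(X_test)
    mse = float(np.mean((pred - yv) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        warnings.warn("constant test response: R2 undefined", stacklevel=2)
        return {"mse": mse, "r2": float("nan")}
    return {"mse": mse, "r2": float(1.0 - np.sum((pred - yv) ** 2) / sst)}


def stratified_split(X, y, *, test_size: float = 0.2, seed: int | None = None,
                     n_strata: int = 4):
    """Single stratified train/test split, stratifying on response quantile bins."""
    M, _ = _as_matrix(X)
    yv = _as_vector(y)
    strata = pd.qcut(yv, n_strata, labels=False, duplicates="drop")
    return train_test_split(M, yv, test_size=test_size, stratify=strata,
                            random_state=None if seed is None else int(seed) % (2 ** 31))
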