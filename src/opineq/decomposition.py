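"""Shapley-value attribution of absolute opportunity inequality to circumstances.

The coalition value of a variable subset S is the absolute opportunity
inequality obtained when the environment-only model is *refit* using only the
variables in S:

    v(S) = MLD(fitted values of the model refit on S),   v(empty) = 0,

and each variable's contribution is its Shapley value over these coalition
values, normalised to percentage shares of theta_a = v(full set).  Exact mode
enumerates all 2^k coalitions (feasible for the 13 circumstance covariates
used here); a Monte-Carlo permutation-sampling estimator covers larger k.

For tree-based models a fast surrogate mode mirrors the TreeSHAP shortcut:
per-observation additive attributions are computed from the tree structure
(path-dependent cover weighting, feature-independence convention), coalition
predictions are reconstructed additively from them, and the Shapley run then
needs no retraining.  Exact (refit) mode is the reference; the surrogate is
the cheap approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .inequality import mld
from .models import FittedHealthModel, cit_to_arrays, fit_cit, fit_forest

__all__ = [
    "ContributionTable",
    "AttributionMatrix",
    "LinearRecipe",
    "CitRecipe",
    "ForestRecipe",
    "coalition_value",
    "shapley_exact",
    "shapley_sampled",
    "attribution_matrix",
    "surrogate_inequality_shares",
]


# ---------------------------------------------------------------------------
# model recipes: refit on a covariate subset, return fitted values
# ---------------------------------------------------------------------------

class LinearRecipe:
    """OLS refits on covariate subsets via the precomputed Gram matrix.

    Rank-deficient subsets (e.g. duplicated columns) use the minimum-norm
    solution; fitted values — all that the coalition value needs — are the
    projection and remain well defined.
    """

    family = "linear"

    def __init__(self, X, y, *, offset: float = 0.0):
        X = pd.DataFrame(X)
        self.columns = [str(c) for c in X.columns]
        self._D = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        self._G = self._D.T @ self._D
        self._c = self._D.T @ y
        self._offset = offset

    def fitted_for(self, subset: tuple[int, ...]) -> np.ndarray:
        idx = [0] + [j + 1 for j in subset]
        beta, *_ = np.linalg.lstsq(self._G[np.ix_(idx, idx)], self._c[idx],
                                   rcond=None)
        return self._D[:, idx] @ beta + self._offset


class CitRecipe:
    """Conditional-inference-tree refits on covariate subsets."""

    family = "cit"

    def __init__(self, X, y, **fit_kw):
        X = pd.DataFrame(X)
        self.columns = [str(c) for c in X.columns]
        self._X = X.to_numpy(dtype=float)
        self._y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        self._kw = fit_kw

    def fitted_for(self, subset: tuple[int, ...]) -> np.ndarray:
        if not subset:
            return np.full(len(self._y), self._y.mean())
        model = fit_cit(self._X[:, list(subset)], self._y, **self._kw)
        return model.fitted


class ForestRecipe:
    """Random-forest refits on covariate subsets.

    Exact-mode enumeration retrains 2^k forests, so the per-coalition forest
    is reduced (``n_trees`` default 100) and each coalition reuses one seed
    derived deterministically from the base seed and the subset — an
    approximation knob, documented as such.
    """

    family = "forest"

    def __init__(self, X, y, *, n_trees: int = 100, seed: int = 0, **fit_kw):
        X = pd.DataFrame(X)
        self.columns = [str(c) for c in X.columns]
        self._X = X.to_numpy(dtype=float)
        self._y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        self._n_trees = n_trees
        self._seed = seed
        self._kw = fit_kw

    def fitted_for(self, subset: tuple[int, ...]) -> np.ndarray:
        if not subset:
            return np.full(len(self._y), self._y.mean())
        mask = sum(1 << j for j in subset)
        seed = (self._seed * 1_000_003 + mask) % (2 ** 31)
        kw = dict(self._kw)
        # all subset features are candidates at each split: random feature
        # sub-sampling at small |S| would distort coalition comparability
        kw.setdefault("max_features", len(subset))
        kw["max_features"] = min(kw["max_features"], len(subset))
        with warnings.catch_warnings():
            # reduced-B coalition forests routinely leave rows never out of
            # bag; the per-coalition OOB diagnostic is not used here
            warnings.filterwarnings("ignore", message=".*never out of bag.*")
            model = fit_forest(self._X[:, list(subset)], self._y,
                               n_trees=self._n_trees, seed=seed, **kw)
        return model.fitted


def coalition_value(recipe, subset) -> float:
    """v(S) = MLD of the subset-refit fitted values; v(empty) = 0 exactly."""
    subset = tuple(sorted(subset))
    if not subset:
        return 0.0
    try:
        return mld(recipe.fitted_for(subset))
    except Exception as err:
        raise RuntimeError(f"coalition {subset} refit failed: {err}") from err


# ---------------------------------------------------------------------------
# contribution tables
# ---------------------------------------------------------------------------

@dataclass
class ContributionTable:
    """Per-variable Shapley contributions to theta_a and percentage shares."""

    variables: list[str]
    phi: np.ndarray
    theta_a: float
    method: str  # exact | sampled | surrogate
    family: str = ""
    n_evaluations: int = 0
    se: np.ndarray | None = None

    @property
    def shares(self) -> np.ndarray:
        """Percentage shares; may be slightly negative, never clipped.
        NaN when theta_a is zero (no inequality to attribute)."""
        if self.theta_a == 0.0:
            return np.full(len(self.phi), np.nan)
        return 100.0 * self.phi / self.theta_a

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"variable": self.variables, "phi": self.phi,
                            "share_pct": self.shares})
        if self.se is not None:
            out["se"] = self.se
        return out


def _shapley_weights(k: int) -> np.ndarray:
    # w[s] applies to a coalition of size s not containing the entering player
    fact = [math.factorial(i) for i in range(k + 1)]
    return np.array([fact[s] * fact[k - 1 - s] / fact[k] for s in range(k)])


def shapley_exact(recipe, *, exact_limit: int = 13,
                  values: np.ndarray | None = None) -> ContributionTable:
    """Exact Shapley decomposition by enumeration of all 2^k coalitions.

    ``values`` may supply precomputed coalition values indexed by bitmask
    (used by the surrogate mode); otherwise every coalition is evaluated via
    ``recipe.fitted_for`` with caching.
    """
    cols = list(recipe.columns)
    k = len(cols)
    if k > exact_limit:
        raise ValueError(
            f"k={k} exceeds the exact-mode limit {exact_limit}; use "
            "shapley_sampled or the surrogate mode")
    n_masks = 1 << k
    if values is None:
        values = np.empty(n_masks)
        for mask in range(n_masks):
            subset = tuple(j for j in range(k) if mask >> j & 1)
            values[mask] = coalition_value(recipe, subset)
    pc = np.array([bin(m).count("1") for m in range(n_masks)])
    w = _shapley_weights(k)
    phi = np.empty(k)
    idx = np.arange(n_masks)
    for j in range(k):
        without = idx[(idx >> j) & 1 == 0]
        phi[j] = float(np.sum(w[pc[without]] * (values[without | (1 << j)] - values[without])))
    return ContributionTable(variables=cols, phi=phi, theta_a=float(values[-1]),
                             method="exact", family=getattr(recipe, "family", ""),
                             n_evaluations=n_masks)


def shapley_sampled(recipe, *, n_perm: int = 2000,
                    seed: int | None = None) -> ContributionTable:
    """Monte-Carlo permutation-sampling Shapley estimate with standard errors.

    Unbiased for the exact value; if ``n_perm`` is at least k! (and k is small
    enough to enumerate) all distinct permutations are visited exactly once
    and the estimate coincides with the exact decomposition.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols = list(recipe.columns)
    k = len(cols)
    rng = np.random.default_rng(seed)
    cache: dict[int, float] = {0: 0.0}

    def value(mask: int) -> float:
        if mask not in cache:
            subset = tuple(j for j in range(k) if mask >> j & 1)
            cache[mask] = coalition_value(recipe, subset)
        return cache[mask]

    if k <= 8 and n_perm >= math.factorial(k):
        perms = list(permutations(range(k)))
    else:
        perms = [rng.permutation(k) for _ in range(n_perm)]
    marginals = np.zeros((len(perms), k))
    for i, perm in enumerate(perms):
        mask = 0
        for j in perm:
            new = mask | (1 << j)
            marginals[i, j] = value(new) - value(mask)
            mask = new
    phi = marginals.mean(axis=0)
    se = marginals.std(axis=0, ddof=1) / np.sqrt(len(perms)) if len(perms) > 1 \
        else np.full(k, np.nan)
    return ContributionTable(variables=cols, phi=phi, theta_a=value((1 << k) - 1),
                             method="sampled", family=getattr(recipe, "family", ""),
                             n_evaluations=len(cache), se=se)


# ---------------------------------------------------------------------------
# tree-structure attributions (TreeSHAP-style, path-dependent)
# ---------------------------------------------------------------------------

@dataclass
class AttributionMatrix:
    """Per-observation, per-feature additive attributions plus a base value.

    Local accuracy: ``base + values[i].sum() == prediction_i`` for every row.
    """

    values: np.ndarray  # (n, k)
    base: float
    columns: list[str] = field(default_factory=list)


def _sklearn_tree_arrays(tree) -> dict:
    t = tree.tree_
    return {"children_left": t.children_left, "children_right": t.children_right,
            "feature": t.feature, "threshold": t.threshold,
            "value": t.value[:, 0, 0], "cover": t.weighted_n_node_samples}


def _tree_attributions(arr: dict, X: np.ndarray, max_path_features: int = 14):
    """Exact Shapley attributions of one tree's path-dependent expectation game.

    For the coalition game ``v_x(S) = E[f(x') | x'_S = x_S]`` estimated by
    cover-weighted tree descent (features outside S average the children by
    their training cover; repeated features on a path multiply edge-wise),
    each leaf contributes a subgame that depends only on the unique features
    along its path.  Leaf subgames are solved by subset enumeration over
    those features (at most the tree depth) and summed — linearity of the
    Shapley value in the game.  Complexity O(L * 2^depth) vectorised over
    observations; equal to the path-dependent TreeSHAP value.
    """
    n, k = X.shape
    phi = np.zeros((n, k))
    base = 0.0
    cl, cr = arr["children_left"], arr["children_right"]
    feat, thr, val, cover = arr["feature"], arr["threshold"], arr["value"], arr["cover"]
    root_cover = cover[0]

    stack = [(0, [])]  # (node, edges); edge = (feature, indicator (n,), cover fraction)
    while stack:
        node, edges = stack.pop()
        if cl[node] < 0:  # leaf
            base += val[node] * cover[node] / root_cover
            _accumulate_leaf(phi, edges, float(val[node]))
            continue
        f, t = int(feat[node]), thr[node]
        go_left = X[:, f] <= t
        frac_l = cover[cl[node]] / cover[node]
        stack.append((cl[node], edges + [(f, go_left, frac_l)]))
        stack.append((cr[node], edges + [(f, ~go_left, 1.0 - frac_l)]))

    return phi, base


def _accumulate_leaf(phi: np.ndarray, edges: list, leaf_value: float) -> None:
    if not edges:
        return
    # merge repeated features: indicators AND together, cover fractions multiply
    merged: dict[int, list] = {}
    for f, ind, frac in edges:
        if f in merged:
            merged[f][0] = merged[f][0] & ind
            merged[f][1] *= frac
        else:
            merged[f] = [ind.copy(), frac]
    feats = list(merged)
    m = len(feats)
    inds = [merged[f][0].astype(float) for f in feats]
    fracs = np.array([merged[f][1] for f in feats])
    n = len(inds[0])
    ratios = [inds[b] / fracs[b] for b in range(m)]
    # g[mask] = prod_{j in mask} ind_j * prod_{j not in mask} frac_j
    g = np.empty((1 << m, n))
    g[0] = np.prod(fracs)
    for mask in range(1, 1 << m):
        b = (mask & -mask).bit_length() - 1  # lowest set bit
        g[mask] = g[mask ^ (1 << b)] * ratios[b]
    w = _shapley_weights(m)
    pc = np.array([bin(x).count("1") for x in range(1 << m)])
    for j in range(m):
        bit = 1 << j
        contrib = np.zeros(n)
        for mask in range(1 << m):
            if mask & bit:
                continue
            contrib += w[pc[mask]] * (g[mask | bit] - g[mask])
        phi[:, feats[j]] += leaf_value * contrib


def attribution_matrix(model, X) -> AttributionMatrix:
    """Per-observation additive attributions for a tree-based health model.

    Supports the conditional inference tree and the random forest (forest
    attributions are the average over trees).  Raises for non-tree models.
    """
    Xdf = pd.DataFrame(X)
    cols = [str(c) for c in Xdf.columns]
    M = Xdf.to_numpy(dtype=float)
    if isinstance(model, FittedHealthModel):
        if model.family == "cit":
            trees = [cit_to_arrays(model.root)]
        elif model.family == "forest":
            trees = [_sklearn_tree_arrays(t) for t in model.sk_model.estimators_]
        else:
            raise TypeError(f"attribution_matrix supports tree models only, "
                            f"got family {model.family!r}")
        if model.columns and len(model.columns) != M.shape[1]:
            raise ValueError("X has a different number of columns than the model")
    elif hasattr(model, "estimators_"):
        trees = [_sklearn_tree_arrays(t) for t in model.estimators_]
    elif hasattr(model, "tree_"):
        trees = [_sklearn_tree_arrays(model)]
    else:
        raise TypeError("attribution_matrix supports tree models only")
    phi = np.zeros((len(M), M.shape[1]))
    base = 0.0
    for arr in trees:
        p, b = _tree_attributions(arr, M)
        phi += p
        base += b
    phi /= len(trees)
    base /= len(trees)
    return AttributionMatrix(values=phi, base=float(base), columns=cols)


# ---------------------------------------------------------------------------
# surrogate inequality shares from an attribution matrix
# ---------------------------------------------------------------------------

def surrogate_inequality_shares(attrib: AttributionMatrix, *, shift: float = 0.0,
                                eps: float = 1e-9) -> ContributionTable:
    """Shapley inequality shares without retraining, from additive attributions.

    Surrogate coalition predictions are rebuilt additively,
    ``h_i(S) = base + sum_{j in S} phi_ij (+ shift)``, their MLD (minus the
    zero of the empty coalition) defines the coalition value, and the Shapley
    run enumerates coalitions exactly — cheap because no model is refit.
    If any surrogate prediction is non-positive the shift is escalated with a
    warning (MLD needs positive values).
    """
    phi = attrib.values
    n, k = phi.shape
    lower = attrib.base + shift + np.minimum(phi, 0.0).sum(axis=1).min()
    if lower <= 0:
        bump = eps - lower
        warnings.warn(f"non-positive surrogate predictions; escalating shift "
                      f"by {bump:.6g}", stacklevel=2)
        shift = shift + bump
    n_masks = 1 << k
    values = np.empty(n_masks)
    values[0] = 0.0
    h = np.full(n, attrib.base + shift)
    prev_gray = 0
    for i in range(1, n_masks):
        gray = i ^ (i >> 1)
        bit = gray ^ prev_gray
        j = bit.bit_length() - 1
        if gray & bit:
            h = h + phi[:, j]
        else:
            h = h - phi[:, j]
        values[gray] = mld(h)
        prev_gray = gray

    class _Precomputed:
        columns = attrib.columns or [f"x{j}" for j in range(k)]
        family = "surrogate"

    table = shapley_exact(_Precomputed(), exact_limit=max(13, k), values=values)
    table.method = "surrogate"
    return table
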