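"""Reference suitability learners behind one fit/predict contract.

Ensemble distribution modelling combines many algorithm families.  Three
representative families are implemented here from first principles, as
scikit-learn style estimators (``fit`` / ``predict_suitability``,
``get_params``, trailing-underscore fitted attributes):

``EnvelopeModel``
    the classic rectilinear climate envelope (BIOCLIM / surface range
    envelope): suitable iff every predictor falls inside the presence-site
    quantile interval ``[q, 1-q]``.

``LogisticModel``
    binomial GLM with logit link, optionally with squared terms, fitted by
    iteratively reweighted least squares on standardised predictors with a
    small ridge stabiliser.

``BaggedTreesModel``
    bagged CART: bootstrap-resampled binary trees with Gini-impurity splits
    over a random subset of variables per node (the random-forest archetype);
    the score is the mean of per-tree leaf presence fractions.

All families emit suitability scores in [0, 1] and refit bit-identically
under the same seed.  Additional algorithms plug in through
:func:`register_learner` and participate in evaluation and consensus without
further code change.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grid_core import RasterLayer, RasterStack

__all__ = [
    "FitError",
    "ModelContractError",
    "SuitabilityModel",
    "EnvelopeModel",
    "LogisticModel",
    "BaggedTreesModel",
    "LEARNER_REGISTRY",
    "register_learner",
    "make_learner",
    "predict_raster",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


class FitError(ValueError):
    """The training data cannot support a fit (e.g. no presences)."""


class ModelContractError(ValueError):
    """Prediction input does not satisfy the fitted model's contract."""


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return arr, None


class SuitabilityModel(BaseEstimator):
    """Common behaviour: feature bookkeeping and the [0, 1] score contract."""

    feature_names_in_: list[str] | None

    def _fit_X(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        arr, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != arr.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
        self.feature_names_in_ = names
        self.n_features_in_ = arr.shape[1]
        return arr, y

    def _predict_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ModelContractError(
                    f"prediction input is missing variable(s) {missing}"
                )
            X = X[self.feature_names_in_]
        arr, _ = _as_matrix(X)
        if arr.shape[1] != self.n_features_in_:
            raise ModelContractError(
                f"model was fitted on {self.n_features_in_} variables, "
                f"got {arr.shape[1]}"
            )
        return arr

    # subclasses implement fit(X, y) and predict_suitability(X)

    def predict(self, X) -> np.ndarray:
        """Alias of :meth:`predict_suitability` (regressor-style)."""
        return self.predict_suitability(X)


class EnvelopeModel(SuitabilityModel):
    """Rectilinear presence envelope (BIOCLIM-style surface range envelope).

    Per variable, the envelope is the ``[q, 1-q]`` quantile interval of the
    presence-site values (linear interpolation of order statistics; the
    conventional 95% envelope at the default ``q = 0.025``).  A point scores
    1 iff it lies inside every interval, else 0.
    """

    def __init__(self, q: float = 0.025):
        self.q = q

    def fit(self, X, y) -> "EnvelopeModel":
        if not 0 <= self.q < 0.5:
            raise ValueError("envelope quantile q must be in [0, 0.5)")
        arr, y = self._fit_X(X, y)
        pres = arr[y == 1.0]
        if len(pres) == 0:
            raise FitError("envelope fit requires at least one presence row")
        if arr.shape[1] == 0:
            raise FitError("envelope fit requires at least one variable")
        self.lower_ = np.quantile(pres, self.q, axis=0, method="linear")
        self.upper_ = np.quantile(pres, 1.0 - self.q, axis=0, method="linear")
        return self

    def predict_suitability(self, X) -> np.ndarray:
        arr = self._predict_X(X)
        inside = (arr >= self.lower_) & (arr <= self.upper_)
        return inside.all(axis=1).astype(float)


class LogisticModel(SuitabilityModel):
    """Binomial GLM (logit link) by IRLS on standardised predictors.

    ``degree=2`` appends squared terms of the standardised predictors.  A
    ridge term ``ridge`` (default 1e-8) on the normal equations stabilises
    near-separated fits; under complete separation the fit converges to the
    ridge-regularised solution and ``separation_warning_`` is set.
    """

    def __init__(self, degree: int = 1, ridge: float = 1e-8,
                 max_iter: int = 200, tol: float = 1e-8):
        self.degree = degree
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol

    def _design(self, z: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(z))]
        if z.shape[1]:
            cols.append(z)
            if self.degree == 2:
                cols.append(z ** 2)
        return np.column_stack(cols)

    def fit(self, X, y) -> "LogisticModel":
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        arr, y = self._fit_X(X, y)
        if not (np.any(y == 0) and np.any(y == 1)):
            raise FitError("logistic fit requires both classes")
        self.mean_ = arr.mean(axis=0) if arr.shape[1] else np.empty(0)
        std = arr.std(axis=0) if arr.shape[1] else np.empty(0)
        self.scale_ = np.where(std > 0, std, 1.0)
        z = (arr - self.mean_) / self.scale_
        Z = self._design(z)
        k = Z.shape[1]

        beta = np.zeros(k)
        converged = False
        for _ in range(self.max_iter):
            eta = np.clip(Z @ beta, -30.0, 30.0)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(p * (1.0 - p), 1e-12)
            # weighted least squares on the working response
            zw = eta + (y - p) / w
            A = (Z * w[:, None]).T @ Z + self.ridge * np.eye(k)
            b = (Z * w[:, None]).T @ zw
            new = np.linalg.solve(A, b)
            delta = np.max(np.abs(new - beta))
            beta = new
            if delta < self.tol:
                converged = True
                break
        self.converged_ = converged
        # |beta| ~ 10 on the standardised scale means near-infinite odds
        # ratios: the data are (close to) separated and the fit is only
        # pinned down by the ridge term
        self.separation_warning_ = bool(np.max(np.abs(beta)) > 10.0) or not converged
        self.coef_all_ = beta
        self.intercept_ = float(beta[0])
        p_feat = arr.shape[1]
        self.coef_ = beta[1:1 + p_feat].copy()
        self.coef2_ = beta[1 + p_feat:].copy() if self.degree == 2 else np.zeros(0)
        return self

    def predict_suitability(self, X) -> np.ndarray:
        arr = self._predict_X(X)
        z = (arr - self.mean_) / self.scale_ if arr.shape[1] else arr
        eta = np.clip(self._design(z) @ self.coef_all_, -30.0, 30.0)
        return 1.0 / (1.0 + np.exp(-eta))


def _gini_best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (weighted Gini, threshold) for one variable, or None.

    Candidate cuts are midpoints between consecutive distinct sorted values;
    both children must hold at least ``min_leaf`` rows.  Ties on impurity
    resolve to the smallest threshold (left-to-right scan).
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cum1 = np.cumsum(ys)
    total1 = cum1[-1]
    k = np.arange(1, n)  # size of left child for a cut after position k-1
    valid = (xs[1:] != xs[:-1]) & (k >= min_leaf) & (n - k >= min_leaf)
    if not valid.any():
        return None
    nL = k[valid].astype(float)
    nR = n - nL
    oneL = cum1[:-1][valid]
    oneR = total1 - oneL
    pL, pR = oneL / nL, oneR / nR
    gini = (nL * 2 * pL * (1 - pL) + nR * 2 * pR * (1 - pR)) / n
    best = int(np.argmin(gini))  # first minimum -> smallest threshold
    cut_idx = k[valid][best]
    thr = 0.5 * (xs[cut_idx - 1] + xs[cut_idx])
    return float(gini[best]), thr


class BaggedTreesModel(SuitabilityModel):
    """Bagged CART trees with Gini splits over random variable subsets.

    Each of ``n_trees`` trees is grown on a bootstrap resample of size n
    (with replacement, tree t seeded as ``seed + t``), with greedy binary
    splits minimising weighted Gini impurity over ``m_try`` randomly chosen
    variables per node (default ``floor(sqrt(p))``), stopping at ``max_depth``
    or when a child would fall below ``min_leaf`` rows.  Leaves store the
    presence fraction; the model score is the across-tree mean.
    """

    def __init__(self, n_trees: int = 50, max_depth: int = 8, min_leaf: int = 5,
                 m_try: int | None = None, seed: int = 0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.m_try = m_try
        self.seed = seed

    def _grow(self, X, y, idx, depth, rng, m_try):
        node_y = y[idx]
        p_hat = float(node_y.mean())
        if (
            depth >= self.max_depth
            or len(idx) < 2 * self.min_leaf
            or p_hat in (0.0, 1.0)
        ):
            return {"leaf": p_hat}
        p = X.shape[1]
        cand = rng.choice(p, size=min(m_try, p), replace=False)
        parent_gini = 2 * p_hat * (1 - p_hat)
        best = None  # (gini, var, thr)
        for j in cand:
            res = _gini_best_split(X[idx, j], node_y, self.min_leaf)
            if res is None:
                continue
            gini, thr = res
            if best is None or gini < best[0] - 1e-15:
                best = (gini, int(j), thr)
        if best is None or best[0] >= parent_gini - 1e-12:
            return {"leaf": p_hat}
        _, j, thr = best
        left = idx[X[idx, j] <= thr]
        right = idx[X[idx, j] > thr]
        return {
            "var": j,
            "thr": thr,
            "left": self._grow(X, y, left, depth + 1, rng, m_try),
            "right": self._grow(X, y, right, depth + 1, rng, m_try),
        }

    def fit(self, X, y) -> "BaggedTreesModel":
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        arr, y = self._fit_X(X, y)
        n = len(y)
        if n < 2 * self.min_leaf:
            raise FitError(
                f"bagged trees need at least {2 * self.min_leaf} rows, got {n}"
            )
        if arr.shape[1] == 0:
            raise FitError("bagged trees require at least one variable")
        m_try = self.m_try or max(1, int(np.sqrt(arr.shape[1])))
        self.m_try_ = m_try
        self.trees_ = []
        for t in range(self.n_trees):
            rng = np.random.default_rng(self.seed + t)
            boot = rng.integers(0, n, size=n)
            Xb, yb = arr[boot], y[boot]
            self.trees_.append(
                self._grow(Xb, yb, np.arange(n), 0, rng, m_try)
            )
        return self

    @staticmethod
    def _predict_tree(node, X, out, idx):
        if "leaf" in node:
            out[idx] = node["leaf"]
            return
        go_left = X[idx, node["var"]] <= node["thr"]
        BaggedTreesModel._predict_tree(node["left"], X, out, idx[go_left])
        BaggedTreesModel._predict_tree(node["right"], X, out, idx[~go_left])

    def predict_suitability(self, X) -> np.ndarray:
        arr = self._predict_X(X)
        total = np.zeros(len(arr))
        scratch = np.empty(len(arr))
        idx = np.arange(len(arr))
        for tree in self.trees_:
            self._predict_tree(tree, arr, scratch, idx)
            total += scratch
        return total / len(self.trees_)


# ---------------------------------------------------------------------------
# Registry and raster prediction
# ---------------------------------------------------------------------------

LEARNER_REGISTRY: dict[str, type] = {
    "envelope": EnvelopeModel,
    "logistic": LogisticModel,
    "bagged_trees": BaggedTreesModel,
}


def register_learner(name: str, cls: type) -> None:
    """Register a plug-in learner; it must expose fit and predict_suitability."""
    for attr in ("fit", "predict_suitability"):
        if not callable(getattr(cls, attr, None)):
            raise TypeError(f"learner {name!r} lacks a callable {attr}()")
    LEARNER_REGISTRY[name] = cls


def make_learner(family: str, **hyperparameters) -> SuitabilityModel:
    if family not in LEARNER_REGISTRY:
        raise KeyError(
            f"unknown learner family {family!r}; known: {sorted(LEARNER_REGISTRY)}"
        )
    return LEARNER_REGISTRY[family](**hyperparameters)


def predict_raster(model, stack: RasterStack, name: str = "suitability") -> RasterLayer:
    """Predict suitability on every off-mask cell of a raster stack.

    Uses the model's fitted variable names (raster prediction at cell centres
    matches row-wise prediction exactly: same code path).
    """
    features = model.feature_names_in_ or stack.names[: model.n_features_in_]
    missing = [f for f in features if f not in stack]
    if missing:
        raise ModelContractError(f"stack is missing variable(s) {missing}")
    sub = stack.subset(features)
    mask = sub.combined_mask()
    rows, cols = np.nonzero(~mask)
    design = pd.DataFrame({f: sub[f].values[rows, cols] for f in features})
    scores = model.predict_suitability(design)
    values = np.zeros(stack.grid.shape)
    values[rows, cols] = scores
    return RasterLayer(name, stack.grid, values, mask)


# ---------------------------------------------------------------------------
# JSON serialization (documented schema)
# ---------------------------------------------------------------------------
#
# {"family": str, "hyperparameters": {...}, "features": [...] | null,
#  "fitted": {...family-specific...}}
#
#  envelope:     {"lower": [...], "upper": [...]}
#  logistic:     {"mean": [...], "scale": [...], "coef_all": [...],
#                 "converged": bool, "separation_warning": bool}
#  bagged_trees: {"m_try": int, "trees": [nested {var,thr,left,right}|{leaf}]}


def model_to_dict(model: SuitabilityModel) -> dict:
    family = next(
        (k for k, v in LEARNER_REGISTRY.items() if type(model) is v), None
    )
    if family is None:
        raise TypeError(f"{type(model).__name__} is not a registered learner")
    out = {
        "family": family,
        "hyperparameters": model.get_params(),
        "features": model.feature_names_in_,
    }
    if isinstance(model, EnvelopeModel):
        out["fitted"] = {
            "lower": model.lower_.tolist(),
            "upper": model.upper_.tolist(),
        }
    elif isinstance(model, LogisticModel):
        out["fitted"] = {
            "mean": model.mean_.tolist(),
            "scale": model.scale_.tolist(),
            "coef_all": model.coef_all_.tolist(),
            "converged": model.converged_,
            "separation_warning": model.separation_warning_,
        }
    elif isinstance(model, BaggedTreesModel):
        out["fitted"] = {"m_try": model.m_try_, "trees": model.trees_}
    else:  # pragma: no cover - registry guard above
        raise TypeError(type(model).__name__)
    return out


def model_from_dict(payload: dict) -> SuitabilityModel:
    model = make_learner(payload["family"], **payload["hyperparameters"])
    model.feature_names_in_ = payload["features"]
    fitted = payload["fitted"]
    if isinstance(model, EnvelopeModel):
        model.lower_ = np.asarray(fitted["lower"], dtype=float)
        model.upper_ = np.asarray(fitted["upper"], dtype=float)
        model.n_features_in_ = len(model.lower_)
    elif isinstance(model, LogisticModel):
        model.mean_ = np.asarray(fitted["mean"], dtype=float)
        model.scale_ = np.asarray(fitted["scale"], dtype=float)
        model.coef_all_ = np.asarray(fitted["coef_all"], dtype=float)
        model.converged_ = bool(fitted["converged"])
        model.separation_warning_ = bool(fitted["separation_warning"])
        model.n_features_in_ = len(model.mean_)
        p = model.n_features_in_
        model.intercept_ = float(model.coef_all_[0])
        model.coef_ = model.coef_all_[1:1 + p].copy()
        model.coef2_ = model.coef_all_[1 + p:].copy()
    elif isinstance(model, BaggedTreesModel):
        model.m_try_ = int(fitted["m_try"])
        model.trees_ = fitted["trees"]
        model.n_features_in_ = (
            len(model.feature_names_in_) if model.feature_names_in_ else 0
        )
    return model


def save_model(model: SuitabilityModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> SuitabilityModel:
    return model_from_dict(json.loads(Path(path).read_text()))
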