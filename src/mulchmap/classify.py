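"""Supervised land-cover classifiers and the train/validation protocol.

Three classifiers are implemented natively:

* **Maximum likelihood (MLC)** — per-class multivariate Gaussian; a pixel x
  is assigned to the class maximising the Bayes discriminant
  ``g_c(x) = ln pi_c - 1/2 ln|Sigma_c| - 1/2 (x-mu_c)' Sigma_c^-1 (x-mu_c)``.
* **Maximum entropy (MaxEnt)** — the least-informative distribution subject
  to feature-expectation constraints, which for linear band features is the
  L2-penalised multinomial logistic model, fitted on z-scored bands.
* **Random forest** — bootstrapped CART trees with Gini-impurity splits on a
  random feature subset per node, majority vote across trees.

The training protocol holds out whole polygons (not pixels) so validation
pixels are spatially disjoint from training pixels.  Hyperparameters are
fixed at one setting per model rather than searched.  Ties everywhere break
to the lowest class index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .geo_io import LabelRaster, MultibandRaster, TrainingSet

UNCLASSIFIED = -1


@dataclass
class SplitSpec:
    """80/20-style split assigning whole polygons per class."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_val(ts: TrainingSet, spec: SplitSpec | None = None
                    ) -> tuple[TrainingSet, TrainingSet]:
    """Split polygons (per class) into train/validation sides.

    Every polygon goes wholly to one side; per class the train side targets
    ``round(train_fraction * n_polygons)`` clamped so both sides keep at
    least one polygon.  Deterministic under the spec seed.
    """
    if spec is None:
        spec = SplitSpec()
    rng = np.random.default_rng(spec.seed)
    train_mask = np.zeros(len(ts), dtype=bool)
    for c in np.unique(ts.y):
        pids = np.unique(ts.polygon_id[ts.y == c])
        if pids.size < 2:
            raise ValueError(
                f"class {ts.class_names[c]!r} has fewer than 2 polygons")
        n_train = int(round(spec.train_fraction * pids.size))
        n_train = min(max(n_train, 1), pids.size - 1)
        chosen = rng.permutation(pids)[:n_train]
        train_mask |= (ts.y == c) & np.isin(ts.polygon_id, chosen)
    return ts.subset(train_mask), ts.subset(~train_mask)


def _raster_pixels(raster: MultibandRaster, band_names) -> tuple:
    """Flattened valid pixel matrix + mask for a band subset."""
    if band_names is not None:
        raster = raster.select_bands(list(band_names))
    valid = raster.valid_mask()
    X = raster.values.reshape(raster.n_bands, -1).T[valid.ravel()]
    return X.astype(float), valid, raster.band_names


def _labels_to_raster(labels_flat, posterior_flat, valid, template,
                      class_names, model_id, band_names) -> "ClassifiedRaster":
    shape = valid.shape
    labels = np.full(shape, UNCLASSIFIED, dtype=np.int16)
    labels[valid] = labels_flat
    posterior = None
    if posterior_flat is not None:
        posterior = np.zeros((posterior_flat.shape[1],) + shape)
        posterior[:, valid] = posterior_flat.T
    return ClassifiedRaster(labels=labels, class_names=list(class_names),
                            transform=template.transform, crs=template.crs,
                            posterior=posterior, model_id=model_id,
                            band_names=list(band_names))


@dataclass
class ClassifiedRaster:
    """Label grid with optional per-class posterior/score grids."""

    labels: np.ndarray
    class_names: list[str]
    transform: object
    crs: str
    posterior: np.ndarray | None = None
    model_id: str = ""
    band_names: list[str] = field(default_factory=list)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def pixel_size(self):
        return self.transform.pixel_size

    def as_label_raster(self) -> LabelRaster:
        return LabelRaster(self.labels.copy(), list(self.class_names),
                           self.transform, self.crs)


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class MLCModel:
    class_names: list[str]
    band_names: list[str]
    means: np.ndarray         # (C, B)
    covariances: np.ndarray   # (C, B, B) after ridge
    log_dets: np.ndarray      # (C,)
    log_priors: np.ndarray    # (C,)
    ridge: float

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """g_c(x) for each sample (rows) and class (columns)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, C = len(X), len(self.class_names)
        g = np.empty((n, C))
        for c in range(C):
            d = X - self.means[c]
            chol = cho_factor(self.covariances[c], lower=True)
            maha = np.sum(d * cho_solve(chol, d.T).T, axis=1)
            g[:, c] = self.log_priors[c] - 0.5 * self.log_dets[c] - 0.5 * maha
        return g

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.discriminants(X), axis=1)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        g = self.discriminants(X)
        return softmax(g, axis=1)


def fit_mlc(train: TrainingSet, priors: str | np.ndarray = "uniform",
            ridge_scale: float = 1e-6) -> MLCModel:
    """Fit per-class sample means/covariances with a diagonal ridge.

    The ridge is ``ridge_scale * mean(diag(Sigma_c))`` per class; classes
    with fewer samples than bands are rescued by the ridge with a warning.
    """
    classes = np.unique(train.y)
    C_all = len(train.class_names)
    B = train.n_bands
    means = np.zeros((C_all, B))
    covs = np.zeros((C_all, B, B))
    log_dets = np.full(C_all, np.inf)
    present = np.zeros(C_all, dtype=bool)
    for c in classes:
        Xc = train.X[train.y == c]
        present[c] = True
        if len(Xc) <= B:
            warnings.warn(
                f"class {train.class_names[c]!r} has {len(Xc)} samples for "
                f"{B} bands; covariance is ridge-regularised")
        means[c] = Xc.mean(axis=0)
        if len(Xc) > 1:
            cov = np.cov(Xc, rowvar=False, ddof=1)
        else:
            cov = np.zeros((B, B))
        cov = np.atleast_2d(cov)
        eps = ridge_scale * max(np.mean(np.diag(cov)), 1e-12)
        cov = cov + eps * np.eye(B)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular covariance for class {train.class_names[c]!r} "
                "after ridge regularisation")
        covs[c] = cov
        log_dets[c] = 2.0 * np.sum(np.log(np.diag(chol)))
    if isinstance(priors, str):
        if priors == "uniform":
            p = present / present.sum()
        elif priors == "frequency":
            counts = np.bincount(train.y, minlength=C_all).astype(float)
            p = counts / counts.sum()
        else:
            raise ValueError(f"unknown priors {priors!r}")
    else:
        p = np.asarray(priors, dtype=float)
        p = p / p.sum()
    with np.errstate(divide="ignore"):
        log_p = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
    # absent classes can never win the argmax
    eye = np.eye(B)
    for c in range(C_all):
        if not present[c]:
            covs[c] = eye
            log_dets[c] = 0.0
            log_p[c] = -np.inf
    return MLCModel(list(train.class_names), list(train.band_names),
                    means, covs, log_dets, log_p, ridge_scale)


def predict_mlc(model: MLCModel, raster: MultibandRaster,
                bands=None, with_posterior: bool = True) -> ClassifiedRaster:
    """Argmax of the Bayes discriminant per valid pixel."""
    band_names = bands if bands is not None else model.band_names
    if list(band_names) != list(model.band_names):
        raise ValueError("band subset does not match the model signature")
    X, valid, used = _raster_pixels(raster, band_names)
    g = model.discriminants(X)
    labels = np.argmax(g, axis=1)
    post = softmax(g, axis=1) if with_posterior else None
    return _labels_to_raster(labels, post, valid, raster, model.class_names,
                             "mlc", used)


# ---------------------------------------------------------------------------
# Maximum entropy (multinomial logistic)
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    converged: bool
    n_iter: int
    grad_norm: float


@dataclass
class MaxEntModel:
    class_names: list[str]
    band_names: list[str]
    weights: np.ndarray       # (C, 1 + B), column 0 = intercept
    feature_mean: np.ndarray  # (B,) z-scoring statistics from training
    feature_std: np.ndarray
    l2: float
    report: ConvergenceReport | None = None

    def _design(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.feature_mean) / self.feature_std
        return np.hstack([np.ones((len(Z), 1)), Z])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self._design(X) @ self.weights.T, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self._design(X) @ self.weights.T, axis=1)


def maxent_objective(w_flat: np.ndarray, Phi: np.ndarray, Y: np.ndarray,
                     l2: float) -> tuple[float, np.ndarray]:
    """Penalised mean negative log-likelihood and its gradient.

    The L2 penalty ``l2/2 * ||W||^2`` covers the whole weight matrix
    (intercept included) so the strong-penalty limit is exactly the uniform
    distribution over classes.
    """
    n, d = Phi.shape
    C = Y.shape[1]
    W = w_flat.reshape(C, d)
    S = Phi @ W.T
    lse = logsumexp(S, axis=1)
    loglik = np.sum(S[Y.astype(bool)]) - np.sum(lse)
    P = softmax(S, axis=1)
    grad = ((P - Y).T @ Phi) / n + l2 * W
    obj = -loglik / n + 0.5 * l2 * np.sum(W * W)
    return obj, grad.ravel()


def fit_maxent(train: TrainingSet, l2: float = 1e-4, tol: float = 1e-8,
               max_iter: int = 500) -> MaxEntModel:
    """Fit the penalised multinomial logistic model with L-BFGS."""
    classes = np.unique(train.y)
    if classes.size < 2:
        raise ValueError("maximum entropy fitting requires >= 2 classes")
    C = len(train.class_names)
    mu = train.X.mean(axis=0)
    sd = train.X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (train.X - mu) / sd
    Phi = np.hstack([np.ones((len(Z), 1)), Z])
    Y = np.zeros((len(Z), C))
    Y[np.arange(len(Z)), train.y] = 1.0
    w0 = np.zeros(C * Phi.shape[1])
    res = minimize(maxent_objective, w0, args=(Phi, Y, l2), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol, "ftol": 0.0})
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = grad_norm <= max(tol, 1e-6)
    if not converged:
        warnings.warn(f"MaxEnt did not reach gradient tolerance "
                      f"(|grad|_inf = {grad_norm:.2e}); returning best "
                      "iterate")
    report = ConvergenceReport(converged, int(res.nit), grad_norm)
    W = res.x.reshape(C, Phi.shape[1])
    return MaxEntModel(list(train.class_names), list(train.band_names),
                       W, mu, sd, l2, report)


def predict_maxent(model: MaxEntModel, raster: MultibandRaster,
                   bands=None, with_posterior: bool = True
                   ) -> ClassifiedRaster:
    band_names = bands if bands is not None else model.band_names
    if list(band_names) != list(model.band_names):
        raise ValueError("band subset does not match the model signature")
    X, valid, used = _raster_pixels(raster, band_names)
    P = model.predict_proba(X)
    labels = np.argmax(P, axis=1)
    return _labels_to_raster(labels, P if with_posterior else None, valid,
                             raster, model.class_names, "maxent", used)


# ---------------------------------------------------------------------------
# Random forest (bootstrapped CART, Gini splits)
# ---------------------------------------------------------------------------

def _grow_tree(X: np.ndarray, y: np.ndarray, idx: np.ndarray, n_classes: int,
               max_features: int, min_samples_leaf: int, max_depth: int,
               rng: np.random.Generator, depth: int = 0) -> dict:
    counts = np.bincount(y[idx], minlength=n_classes)
    majority = int(np.argmax(counts))  # ties -> lowest class index
    if (counts.max() == counts.sum() or depth >= max_depth
            or idx.size < 2 * min_samples_leaf):
        return {"leaf": majority}
    feats = rng.choice(X.shape[1], size=max_features, replace=False)
    best = None  # (impurity, feature, threshold)
    n = idx.size
    for f in feats:
        v = X[idx, f]
        order = np.argsort(v, kind="mergesort")
        vs = v[order]
        ys = y[idx[order]]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left = np.cumsum(onehot, axis=0)          # counts left of split i+1
        total = left[-1]
        nl = np.arange(1, n + 1, dtype=float)
        nr = n - nl
        with np.errstate(divide="ignore", invalid="ignore"):
            gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
            right = total - left
            gini_r = np.where(nr > 0,
                              1.0 - np.sum((right
                                            / np.maximum(nr, 1)[:, None]) ** 2,
                                           axis=1), 0.0)
        weighted = (nl * gini_l + nr * gini_r) / n
        # candidate split after position i requires a value change there
        valid_split = (vs[1:] > vs[:-1])
        valid_split &= (nl[:-1] >= min_samples_leaf)
        valid_split &= (nr[:-1] >= min_samples_leaf)
        if not valid_split.any():
            continue
        w = np.where(valid_split, weighted[:-1], np.inf)
        i = int(np.argmin(w))
        if best is None or w[i] < best[0]:
            thr = 0.5 * (vs[i] + vs[i + 1])
            best = (w[i], int(f), thr)
    if best is None:
        return {"leaf": majority}
    _, f, thr = best
    mask = X[idx, f] <= thr
    if not mask.any() or mask.all():
        return {"leaf": majority}
    left = _grow_tree(X, y, idx[mask], n_classes, max_features,
                      min_samples_leaf, max_depth, rng, depth + 1)
    right = _grow_tree(X, y, idx[~mask], n_classes, max_features,
                       min_samples_leaf, max_depth, rng, depth + 1)
    return {"feature": f, "threshold": thr, "left": left, "right": right}


def _tree_predict(node: dict, X: np.ndarray, out: np.ndarray,
                  idx: np.ndarray) -> None:
    if "leaf" in node:
        out[idx] = node["leaf"]
        return
    mask = X[idx, node["feature"]] <= node["threshold"]
    _tree_predict(node["left"], X, out, idx[mask])
    _tree_predict(node["right"], X, out, idx[~mask])


@dataclass
class ForestModel:
    class_names: list[str]
    band_names: list[str]
    trees: list[dict]
    features_per_split: int
    seed: int

    def votes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_classes = len(self.class_names)
        votes = np.zeros((len(X), n_classes), dtype=np.int32)
        pred = np.empty(len(X), dtype=np.int64)
        all_idx = np.arange(len(X))
        for tree in self.trees:
            _tree_predict(tree, X, pred, all_idx)
            votes[all_idx, pred] += 1
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.votes(X), axis=1)  # ties -> lowest index

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        v = self.votes(X).astype(float)
        return v / v.sum(axis=1, keepdims=True)


def fit_rf(train: TrainingSet, n_trees: int = 500,
           features_per_split: int | None = None, seed: int = 0,
           min_samples_leaf: int = 1, max_depth: int = 64) -> ForestModel:
    """Grow a bootstrapped forest of Gini-split CART trees."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    B = train.n_bands
    if features_per_split is None:
        features_per_split = max(1, int(np.floor(np.sqrt(B))))
    features_per_split = min(features_per_split, B)
    rng = np.random.default_rng(seed)
    X = train.X
    y = train.y
    n_classes = len(train.class_names)
    trees = []
    for _ in range(n_trees):
        idx = rng.integers(0, len(X), size=len(X))
        trees.append(_grow_tree(X, y, idx, n_classes, features_per_split,
                                min_samples_leaf, max_depth, rng))
    return ForestModel(list(train.class_names), list(train.band_names),
                       trees, features_per_split, seed)


def predict_rf(model: ForestModel, raster: MultibandRaster,
               bands=None, with_posterior: bool = False) -> ClassifiedRaster:
    band_names = bands if bands is not None else model.band_names
    if list(band_names) != list(model.band_names):
        raise ValueError("band subset does not match the model signature")
    X, valid, used = _raster_pixels(raster, band_names)
    votes = model.votes(X)
    labels = np.argmax(votes, axis=1)
    post = None
    if with_posterior:
        post = votes.astype(float) / votes.sum(axis=1, keepdims=True)
    return _labels_to_raster(labels, post, valid, raster, model.class_names,
                             "rf", used)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialise any of the three model types to JSON."""
    if isinstance(model, MLCModel):
        doc = {"kind": "mlc", "class_names": model.class_names,
               "band_names": model.band_names,
               "means": model.means.tolist(),
               "covariances": model.covariances.tolist(),
               "log_dets": model.log_dets.tolist(),
               "log_priors": [None if not np.isfinite(v) else v
                              for v in model.log_priors],
               "ridge": model.ridge}
    elif isinstance(model, MaxEntModel):
        doc = {"kind": "maxent", "class_names": model.class_names,
               "band_names": model.band_names,
               "weights": model.weights.tolist(),
               "feature_mean": model.feature_mean.tolist(),
               "feature_std": model.feature_std.tolist(), "l2": model.l2}
    elif isinstance(model, ForestModel):
        doc = {"kind": "rf", "class_names": model.class_names,
               "band_names": model.band_names, "trees": model.trees,
               "features_per_split": model.features_per_split,
               "seed": model.seed}
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc["kind"]
    if kind == "mlc":
        return MLCModel(doc["class_names"], doc["band_names"],
                        np.array(doc["means"]), np.array(doc["covariances"]),
                        np.array(doc["log_dets"]),
                        np.array([-np.inf if v is None else v
                                  for v in doc["log_priors"]]),
                        doc["ridge"])
    if kind == "maxent":
        return MaxEntModel(doc["class_names"], doc["band_names"],
                           np.array(doc["weights"]),
                           np.array(doc["feature_mean"]),
                           np.array(doc["feature_std"]), doc["l2"])
    if kind == "rf":
        return ForestModel(doc["class_names"], doc["band_names"],
                           doc["trees"], doc["features_per_split"],
                           doc["seed"])
    raise ValueError(f"unknown model kind {kind!r}")
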