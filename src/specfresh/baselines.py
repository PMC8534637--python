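"""Chemometric baseline classifiers and train-only preprocessing.

Three conventional models — RBF-kernel SVM, random forest, and PLS-DA — each
optionally preceded by one of the classical spectral preprocessing steps:
column standardization, sliding-window smoothing, or PCA feature reduction.
Every preprocessing statistic is learned on the training rows only and then
applied unchanged to held-out data (no leakage by construction).

PLS-DA is implemented as PLS regression of a {0, 1}-coded label on the
spectra with a 0.5 decision threshold on the predicted response; a predicted
response exactly at the threshold is resolved toward the positive (fresh)
class, matching the network's tie convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .errors import ConfigError, NotFittedError

BASELINE_NAMES = ("svm", "rf", "plsda")

#: default hyperparameter grids (none are dictated by the method itself)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": list(np.logspace(-4, 0, 5)),
    },
    "rf": {"n_trees": [50, 100, 200, 500]},
    "plsda": {"n_components": list(range(1, 16))},
}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def smooth(X: np.ndarray, window: int, method: str = "moving_average") -> np.ndarray:
    """Centered sliding-window smoothing of each spectrum.

    ``moving_average`` (default) is a centered mean whose window shrinks
    (truncates) at the edges, so a window of 1 is the identity and constant
    spectra are unchanged for any window. ``savgol`` applies a 2nd-order
    Savitzky-Golay filter instead (window must then be >= 5).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if window % 2 == 0 or window < 1:
        raise ConfigError("smoothing window must be an odd integer >= 1")
    if window > n:
        raise ConfigError(f"window {window} exceeds spectrum length {n}")
    if method == "savgol":
        if window < 5:
            raise ConfigError("savgol smoothing needs window >= 5")
        return savgol_filter(X, window_length=window, polyorder=2, axis=1)
    if method != "moving_average":
        raise ConfigError(f"unknown smoothing method {method!r}")
    if window == 1:
        return X.copy()
    half = window // 2
    csum = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


class _Standardizer:
    """Column-wise standardization; zero-variance columns map to 0."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def params(self) -> dict:
        return {"mean": self.mean_.copy(), "scale": self.scale_.copy()}


class _Smoother:
    def __init__(self, window: int, method: str = "moving_average"):
        self.window = window
        self.method = method

    def fit(self, X: np.ndarray) -> "_Smoother":
        smooth(X[:1], self.window, self.method)  # validate against n
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return smooth(X, self.window, self.method)

    def params(self) -> dict:
        return {"window": self.window, "method": self.method}


class _PCAReducer:
    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X: np.ndarray) -> "_PCAReducer":
        if self.n_components > min(X.shape):
            raise ConfigError(
                f"pca n_components={self.n_components} exceeds min(X.shape)={min(X.shape)}"
            )
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full").fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca_.transform(X)

    def params(self) -> dict:
        return {
            "components": self.pca_.components_.copy(),
            "mean": self.pca_.mean_.copy(),
        }


_STEP_BUILDERS = {
    "standardize": lambda opts: _Standardizer(),
    "smooth": lambda opts: _Smoother(**opts),
    "pca": lambda opts: _PCAReducer(**opts),
}


@dataclass
class PreprocSpec:
    """Ordered preprocessing chain, fit on training data only.

    ``steps`` is a list of ``(name, options)`` pairs with names drawn from
    ``none | standardize | smooth | pca``. Transform refuses to run before
    fit.
    """

    steps: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for step in self.steps:
            if isinstance(step, str):
                name, opts = step, {}
            else:
                name, opts = step
            if name == "none":
                continue
            if name not in _STEP_BUILDERS:
                raise ConfigError(f"unknown preprocessing step {name!r}")
            norm.append((name, dict(opts)))
        self.steps = norm
        self._fitted: list | None = None

    @property
    def fitted_params(self) -> list | None:
        if self._fitted is None:
            return None
        return [(name, obj.params()) for name, obj in self._fitted]

    def fit(self, X_train: np.ndarray) -> "PreprocSpec":
        fitted = []
        Xc = np.asarray(X_train, dtype=float)
        for name, opts in self.steps:
            obj = _STEP_BUILDERS[name](opts).fit(Xc)
            Xc = obj.transform(Xc)
            fitted.append((name, obj))
        self._fitted = fitted
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._fitted is None:
            raise NotFittedError("preprocessing chain used before fit")
        Xc = np.asarray(X, dtype=float)
        for _, obj in self._fitted:
            Xc = obj.transform(Xc)
        return Xc


# ---------------------------------------------------------------------------
# baseline models
# ---------------------------------------------------------------------------


@dataclass
class BaselineSpec:
    """A baseline family plus its hyperparameter grid."""

    name: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ConfigError(f"unknown baseline {self.name!r}; valid: {BASELINE_NAMES}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.name].items()}
        for key, values in self.grid.items():
            if not values:
                raise ConfigError(f"empty grid for hyperparameter {key!r}")
            if any(v <= 0 for v in values):
                raise ConfigError(f"hyperparameter {key!r} values must be positive")

    def configurations(self) -> list[dict]:
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


class BaselineClassifier:
    """Preprocessing chain + one conventional model, sklearn-style."""

    def __init__(
        self,
        spec_name: str,
        params: dict,
        preproc: PreprocSpec | None = None,
        seed: int = 0,
    ):
        if spec_name not in BASELINE_NAMES:
            raise ConfigError(f"unknown baseline {spec_name!r}")
        self.name = spec_name
        self.params = dict(params)
        # own copy of the chain so shared spec objects are never refit in place
        self.preproc = PreprocSpec(preproc.steps) if preproc is not None else PreprocSpec([])
        self.seed = seed
        self._model = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaselineClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.preproc.fit(X)
        Xt = self.preproc.transform(X)
        self._n_features = X.shape[1]
        if self.name == "svm":
            self._model = SVC(
                kernel="rbf", C=self.params["C"], gamma=self.params["gamma"]
            ).fit(Xt, y)
        elif self.name == "rf":
            self._model = RandomForestClassifier(
                n_estimators=int(self.params["n_trees"]), random_state=self.seed
            ).fit(Xt, y)
        else:  # plsda
            k = int(self.params["n_components"])
            if k > np.linalg.matrix_rank(Xt - Xt.mean(axis=0)):
                raise ConfigError(
                    f"plsda n_components={k} exceeds the rank of the "
                    "(centered) training matrix"
                )
            self._model = PLSRegression(n_components=k).fit(Xt, y.astype(float))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise NotFittedError("baseline classifier used before fit")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._n_features:
            raise ValueError(
                f"expected {self._n_features} columns, got {X.shape[1]}"
            )
        Xt = self.preproc.transform(X)
        if self.name == "plsda":
            resp = np.ravel(self._model.predict(Xt))
            return (resp >= 0.5).astype(int)  # ties resolve to fresh (1)
        return self._model.predict(Xt)


def fit_baseline(
    spec: BaselineSpec,
    preproc: PreprocSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    params: dict,
    seed: int = 0,
) -> BaselineClassifier:
    """Fit one configured baseline with train-only preprocessing."""
    clf = BaselineClassifier(spec.name, params, preproc=preproc, seed=seed)
    return clf.fit(X_train, y_train)


def predict_baseline(classifier: BaselineClassifier, X: np.ndarray) -> np.ndarray:
    return classifier.predict(X)


# convenience wrappers kept for symmetry with the individual operations
def fit_standardizer(X_train: np.ndarray) -> dict:
    return _Standardizer().fit(np.asarray(X_train, dtype=float)).params()


def apply_standardizer(params: dict, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params["mean"]) / params["scale"]
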