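"""The four regression back-ends behind one fit/predict contract.

PLSR and SVR wrap scikit-learn; the CNN and BiLSTM are small numpy
networks (see ``milletnir._nets``) trained with Adam, an initial learning
rate of 0.01 decayed x0.2 every 100 epochs, L2 coefficient 0.01,
gradient-norm clipping at 1 and a 5000-epoch cap with early stopping.
Every model standardizes its inputs internally (PLSR centers), so the
contract is scale-free across amino acids; predictions are returned on the
original target scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._nets import BiLstmRegressor, CnnRegressor, TrainConfig, learning_rate_at

__all__ = [
    "ModelHyperparams",
    "FittedModel",
    "fit_plsr",
    "select_plsr_components",
    "fit_svr",
    "fit_cnn",
    "fit_bilstm",
    "fit_model",
    "MODEL_KINDS",
]

MODEL_KINDS = ("PLSR", "SVR", "CNN", "BiLSTM")

#: Logarithmic CV grid for SVR when hyperparameters are left at "grid".
SVR_GRID = {
    "svr__C": [10.0**k for k in range(-1, 4)],
    "svr__epsilon": [10.0**k for k in range(-4, 0)],
    "svr__gamma": [10.0**k for k in range(-3, 2)],
}


@dataclass
class ModelHyperparams:
    """Hyperparameters for any of the four model kinds.

    String sentinels select data-driven choices: ``plsr_ncomp="cv"`` picks
    the component count by cross-validation; SVR fields set to ``"grid"``
    are tuned by 5-fold grid search over :data:`SVR_GRID`.
    """

    model_kind: str = "PLSR"
    plsr_ncomp: int | str = "cv"
    plsr_max_ncomp: int = 10
    svr_C: float | str = "grid"
    svr_epsilon: float | str = "grid"
    svr_gamma: float | str = "grid"
    cv_folds: int = 5
    nn_max_epochs: int = 5000
    nn_lr0: float = 0.01
    nn_decay_factor: float = 0.2
    nn_decay_every: int = 100
    nn_l2: float = 0.01
    nn_grad_clip: float = 1.0
    nn_patience: int = 200
    cnn_channels: int = 8
    lstm_hidden: int = 16
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.nn_max_epochs,
            lr0=self.nn_lr0,
            decay_factor=self.nn_decay_factor,
            decay_every=self.nn_decay_every,
            l2=self.nn_l2,
            grad_clip=self.nn_grad_clip,
            patience=self.nn_patience,
            seed=self.seed,
        )


@dataclass
class FittedModel:
    """A trained model plus the provenance needed to apply it correctly."""

    model_kind: str
    estimator: Any
    wavelength_indices: np.ndarray | None = None
    target_name: str | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.wavelength_indices is not None and X.shape[1] != len(
            self.wavelength_indices
        ):
            X = X[:, self.wavelength_indices]
        pred = self.estimator.predict(X)
        return np.asarray(pred, dtype=float).ravel()


def fit_plsr(X: np.ndarray, y: np.ndarray, ncomp: int, **meta) -> FittedModel:
    """Partial least squares regression with a fixed component count."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_ok = min(X.shape[1], X.shape[0] - 1)
    if not (1 <= ncomp <= max_ok):
        raise ValueError(f"ncomp must be in [1, {max_ok}], got {ncomp}")
    est = PLSRegression(n_components=ncomp, scale=False)
    est.fit(X, y)
    return FittedModel(
        model_kind="PLSR", estimator=est, metadata={"ncomp": ncomp, **meta}
    )


def select_plsr_components(
    X: np.ndarray,
    y: np.ndarray,
    max_ncomp: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Component count minimizing k-fold RMSECV; ties go to the smallest."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    max_ncomp = min(max_ncomp, X.shape[1], n - 1 - int(np.ceil(n / folds)))
    max_ncomp = max(max_ncomp, 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros(max_ncomp)
    for train, test in kf.split(X):
        for a in range(1, max_ncomp + 1):
            nc = min(a, train.size - 1)
            est = PLSRegression(n_components=nc, scale=False)
            est.fit(X[train], y[train])
            pred = est.predict(X[test]).ravel()
            errors[a - 1] += ((y[test] - pred) ** 2).sum()
    return int(np.argmin(errors)) + 1  # argmin takes the first (smallest) on ties


class _StandardizedTarget:
    """Wrap an estimator to fit/predict on a standardized target."""

    def __init__(self, inner):
        self.inner = inner

    def fit(self, X, y):
        self._mean = float(np.mean(y))
        sd = float(np.std(y))
        self._sd = sd if sd > 0 else 1.0
        self.inner.fit(X, (y - self._mean) / self._sd)
        return self

    def predict(self, X):
        return np.asarray(self.inner.predict(X)).ravel() * self._sd + self._mean


def fit_svr(
    X: np.ndarray, y: np.ndarray, hp: ModelHyperparams | None = None, **meta
) -> FittedModel:
    """Epsilon-insensitive RBF support vector regression.

    Features are standardized in-pipeline and the target internally; any
    hyperparameter left at ``"grid"`` is chosen by seeded k-fold grid
    search over a logarithmic grid.
    """
    hp = hp or ModelHyperparams(model_kind="SVR")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    grid = {}
    fixed = {}
    for key, value in (
        ("svr__C", hp.svr_C),
        ("svr__epsilon", hp.svr_epsilon),
        ("svr__gamma", hp.svr_gamma),
    ):
        if value == "grid":
            grid[key] = SVR_GRID[key]
        else:
            fixed[key] = float(value)
    pipe.set_params(**fixed)
    if grid:
        cv = KFold(n_splits=hp.cv_folds, shuffle=True, random_state=hp.seed)
        search = GridSearchCV(
            pipe, grid, cv=cv, scoring="neg_root_mean_squared_error", n_jobs=1
        )
        est = _StandardizedTarget(search).fit(X, y)
        chosen = search.best_params_
    else:
        est = _StandardizedTarget(pipe).fit(X, y)
        chosen = fixed
    return FittedModel(
        model_kind="SVR", estimator=est, metadata={"hyperparams": chosen, **meta}
    )


def fit_cnn(
    X: np.ndarray, y: np.ndarray, hp: ModelHyperparams | None = None, **meta
) -> FittedModel:
    """1-D convolutional regression over the wavelength axis."""
    hp = hp or ModelHyperparams(model_kind="CNN")
    net = CnnRegressor(hp.train_config(), channels=hp.cnn_channels)
    net.fit(X, y)
    return FittedModel(
        model_kind="CNN",
        estimator=net,
        metadata={"epochs_run": net.epochs_run, "seed": hp.seed, **meta},
    )


def fit_bilstm(
    X: np.ndarray, y: np.ndarray, hp: ModelHyperparams | None = None, **meta
) -> FittedModel:
    """Bidirectional LSTM regression, wavelengths read as a sequence."""
    hp = hp or ModelHyperparams(model_kind="BiLSTM")
    net = BiLstmRegressor(hp.train_config(), hidden=hp.lstm_hidden)
    net.fit(X, y)
    return FittedModel(
        model_kind="BiLSTM",
        estimator=net,
        metadata={"epochs_run": net.epochs_run, "seed": hp.seed, **meta},
    )


def fit_model(
    X: np.ndarray, y: np.ndarray, hp: ModelHyperparams, **meta
) -> FittedModel:
    """Dispatch on ``hp.model_kind`` (PLSR, SVR, CNN or BiLSTM)."""
    kind = hp.model_kind.upper().replace("BILSTM", "BiLSTM")
    if kind == "PLSR":
        if hp.plsr_ncomp == "cv":
            ncomp = select_plsr_components(
                X, y, max_ncomp=hp.plsr_max_ncomp, folds=hp.cv_folds, seed=hp.seed
            )
        else:
            ncomp = int(hp.plsr_ncomp)
        return fit_plsr(X, y, ncomp=ncomp, **meta)
    if kind == "SVR":
        return fit_svr(X, y, hp, **meta)
    if kind == "CNN":
        return fit_cnn(X, y, hp, **meta)
    if kind == "BiLSTM":
        return fit_bilstm(X, y, hp, **meta)
    raise ValueError(f"unknown model kind {hp.model_kind!r}")
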