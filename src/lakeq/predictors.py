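"""Pluggable one-step base forecasters and the model registry.

Each registered forecaster realizes one state/action index of the learning
agent: it is fitted once on the training split and then produces one-step
multivariate forecasts from a trailing history window.  The shipped defaults
are deliberately lightweight — persistence, a multi-output linear
autoregression on the flattened window, and a trailing-window mean — so the
selection mechanism can be exercised quickly on a desk machine.  Heavier
sequence models (recurrent nets, attention nets, deep forests) plug in
through the same contract when their dependencies are installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.linear_model import LinearRegression, RidgeCV

from .series import SeriesMatrix

__all__ = [
    "Forecaster",
    "PersistenceForecaster",
    "WindowMeanForecaster",
    "LinearARForecaster",
    "RidgeARForecaster",
    "ZeroForecaster",
    "ModelRegistry",
    "builtin_models",
    "make_model",
    "one_step_forecast",
]

DEFAULT_WINDOW = 24  # one day of hourly samples

_OPTIONAL_DEPS = {
    "lstm": "torch",
    "transformer": "torch",
    "deep_rf": "deepforest (gcForest-style cascade)",
}


class Forecaster:
    """One-step multivariate forecaster contract.

    Subclasses implement :meth:`fit` (called once on the training split) and
    :meth:`predict_next` (forecast the next s-vector from a ``window``-row
    history).  Both must be deterministic for a fixed fitted state.
    """

    kind: str = "base"

    def __init__(self, name: str, window: int = DEFAULT_WINDOW):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.name = name
        self.window = int(window)

    def fit(self, history: SeriesMatrix) -> "Forecaster":
        return self

    def predict_next(self, window_values: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_at(self, values: np.ndarray, t: int) -> np.ndarray:
        """Forecast row t of ``values`` from the rows immediately before it."""
        if t < self.window:
            raise ValueError(
                f"model '{self.name}' needs {self.window} history rows, "
                f"only {t} available"
            )
        return self.predict_next(values[t - self.window : t])

    # -- state round-trip (JSON-able) ------------------------------------
    def get_state(self) -> dict:
        return {"kind": self.kind, "name": self.name, "window": self.window}

    def set_state(self, state: dict) -> None:
        self.window = int(state["window"])


class PersistenceForecaster(Forecaster):
    """Next value = last observed value."""

    kind = "persistence"

    def __init__(self, name: str = "persistence", window: int = 1):
        super().__init__(name, window)

    def predict_next(self, window_values: np.ndarray) -> np.ndarray:
        return np.asarray(window_values, dtype=float)[-1].copy()


class WindowMeanForecaster(Forecaster):
    """Next value = mean of the trailing window."""

    kind = "window_mean"

    def __init__(self, name: str = "window_mean", window: int = DEFAULT_WINDOW):
        super().__init__(name, window)

    def predict_next(self, window_values: np.ndarray) -> np.ndarray:
        return np.asarray(window_values, dtype=float)[-self.window :].mean(axis=0)


class LinearARForecaster(Forecaster):
    """Multi-output linear autoregression: one least-squares AR(window) map
    per channel from its own trailing lags to its next value.

    Exact on any trajectory affine in its own lags (e.g. a noiseless
    straight line); per-channel fits keep the regression well-posed instead
    of pooling window * s collinear lagged features.
    """

    kind = "linear_ar"

    def __init__(self, name: str = "linear_ar", window: int = DEFAULT_WINDOW):
        super().__init__(name, window)
        self._coef: np.ndarray | None = None       # (s, window)
        self._intercept: np.ndarray | None = None  # (s,)

    def fit(self, history: SeriesMatrix) -> "LinearARForecaster":
        values = history.values
        w = self.window
        if history.n_steps <= w:
            raise ValueError(
                f"linear AR needs more than window={w} rows, got {history.n_steps}"
            )
        s = values.shape[1]
        self._coef = np.empty((s, w))
        self._intercept = np.empty(s)
        for k in range(s):
            X = np.stack([values[t - w : t, k] for t in range(w, history.n_steps)])
            model = LinearRegression().fit(X, values[w:, k])
            self._coef[k] = model.coef_
            self._intercept[k] = model.intercept_
        return self

    def predict_next(self, window_values: np.ndarray) -> np.ndarray:
        if self._coef is None:
            raise RuntimeError(f"model '{self.name}' is not fitted")
        x = np.asarray(window_values, dtype=float)[-self.window :]
        return (self._coef * x.T).sum(axis=1) + self._intercept

    def get_state(self) -> dict:
        state = super().get_state()
        if self._coef is not None:
            state["coef"] = self._coef.tolist()
            state["intercept"] = self._intercept.tolist()
        return state

    def set_state(self, state: dict) -> None:
        super().set_state(state)
        if "coef" in state:
            self._coef = np.asarray(state["coef"], dtype=float)
            self._intercept = np.asarray(state["intercept"], dtype=float)


class RidgeARForecaster(LinearARForecaster):
    """Per-channel ridge autoregression with cross-validated shrinkage.

    Intended for error (residual) series: when the residuals are white the
    selected penalty is large and the forecast collapses toward zero
    correction, so the model is harmless; when the residuals carry
    structure (e.g. decaying transients after level shifts) a small penalty
    is selected and the structure is captured.
    """

    kind = "ridge_ar"

    #: candidate penalties spanning effectively-unpenalized to near-null
    ALPHAS = np.logspace(-3, 5, 17)

    def __init__(self, name: str = "ridge_ar", window: int = 6):
        super().__init__(name, window)

    def fit(self, history: SeriesMatrix) -> "RidgeARForecaster":
        values = history.values
        w = self.window
        if history.n_steps <= w:
            raise ValueError(
                f"ridge AR needs more than window={w} rows, got {history.n_steps}"
            )
        s = values.shape[1]
        self._coef = np.empty((s, w))
        self._intercept = np.empty(s)
        for k in range(s):
            X = np.stack([values[t - w : t, k] for t in range(w, history.n_steps)])
            model = RidgeCV(alphas=self.ALPHAS).fit(X, values[w:, k])
            self._coef[k] = model.coef_
            self._intercept[k] = model.intercept_
        return self


class ZeroForecaster(Forecaster):
    """Always forecasts zero; a null compensation model for error series."""

    kind = "zero"

    def __init__(self, name: str = "zero", window: int = 1):
        super().__init__(name, window)
        self._n_channels: int | None = None

    def fit(self, history: SeriesMatrix) -> "ZeroForecaster":
        self._n_channels = history.n_channels
        return self

    def predict_next(self, window_values: np.ndarray) -> np.ndarray:
        return np.zeros(np.asarray(window_values).shape[1])

    def get_state(self) -> dict:
        state = super().get_state()
        state["n_channels"] = self._n_channels
        return state


_KINDS = {
    cls.kind: cls
    for cls in (
        PersistenceForecaster,
        WindowMeanForecaster,
        LinearARForecaster,
        RidgeARForecaster,
        ZeroForecaster,
    )
}


def make_model(kind: str, window: int = DEFAULT_WINDOW) -> Forecaster:
    """Instantiate a built-in forecaster by kind name."""
    if kind in _OPTIONAL_DEPS:
        raise ImportError(
            f"model '{kind}' requires the optional dependency "
            f"'{_OPTIONAL_DEPS[kind]}', which is not installed; register a "
            "custom Forecaster instead or use the lightweight defaults"
        )
    if kind not in _KINDS:
        raise KeyError(
            f"unknown model kind '{kind}'; available: {sorted(_KINDS)}"
        )
    cls = _KINDS[kind]
    if kind in ("persistence", "zero"):
        return cls()
    return cls(window=window)


class ModelRegistry:
    """Ordered set of forecasters; indices double as state/action labels."""

    def __init__(self, models: list[Forecaster] | None = None):
        self._models: list[Forecaster] = []
        self._by_name: dict[str, int] = {}
        for m in models or []:
            self.register(m)

    def register(self, model: Forecaster) -> "ModelRegistry":
        if model.name in self._by_name:
            raise ValueError(f"duplicate model name '{model.name}'")
        self._by_name[model.name] = len(self._models)
        self._models.append(model)
        return self

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self):
        return iter(self._models)

    def __getitem__(self, index: int) -> Forecaster:
        return self._models[index]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self._models]

    @property
    def max_window(self) -> int:
        if not self._models:
            raise ValueError("empty model registry")
        return max(m.window for m in self._models)

    def index_of(self, name: str) -> int:
        return self._by_name[name]

    def fit_all(self, history: SeriesMatrix) -> "ModelRegistry":
        if not self._models:
            raise ValueError("cannot train with an empty model registry")
        for m in self._models:
            m.fit(history)
        return self

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = [m.get_state() for m in self._models]
        (directory / "models.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, directory) -> "ModelRegistry":
        payload = json.loads((Path(directory) / "models.json").read_text())
        registry = cls()
        for state in payload:
            model = _KINDS[state["kind"]](
                name=state["name"], window=state["window"]
            )
            model.set_state(state)
            registry.register(model)
        return registry


def builtin_models(window: int = DEFAULT_WINDOW) -> list[Forecaster]:
    """The default lightweight model set: persistence, linear AR, window mean."""
    return [
        PersistenceForecaster(),
        LinearARForecaster(window=window),
        WindowMeanForecaster(window=window),
    ]


def one_step_forecast(
    registry: ModelRegistry, action: int, history: SeriesMatrix | np.ndarray
) -> np.ndarray:
    """Dispatch a one-step forecast to the model at ``action``."""
    model = registry[action]
    values = history.values if isinstance(history, SeriesMatrix) else np.asarray(history)
    if len(values) < model.window:
        raise ValueError(
            f"history has {len(values)} rows but model '{model.name}' "
            f"needs {model.window}"
        )
    return model.predict_next(values[-model.window :])
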