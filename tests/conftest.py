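import numpy as np
import pandas as pd
import pytest

from lakeq.predictors import Forecaster
from lakeq.series import SeriesMatrix


def make_series(values, start="2021-07-26", freq="h", names=None) -> SeriesMatrix:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return SeriesMatrix(
        pd.date_range(start, periods=len(values), freq=freq),
        values,
        names or [f"ch{i + 1}" for i in range(values.shape[1])],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    """60 x 3 mildly correlated series for quick structural checks."""
    t = np.arange(60)
    base = np.column_stack([
        10 + 0.1 * t,
        5 + np.sin(2 * np.pi * t / 24),
        3 + 0.05 * t + 0.3 * np.cos(2 * np.pi * t / 24),
    ])
    return make_series(base + 0.05 * rng.standard_normal(base.shape))


class TruthOracle(Forecaster):
    """Test double: forecasts the true next value (needs the full series)."""

    kind = "oracle"

    def __init__(self, name="oracle", bias=0.0):
        super().__init__(name, window=1)
        self.bias = bias
        self._values = None

    def fit(self, history):
        self._values = history.values
        return self

    def predict_at(self, values, t):
        return values[t] + self.bias

    def predict_next(self, window_values):  # pragma: no cover - rolling only
        return np.asarray(window_values)[-1] + self.bias


@pytest.fixture
def oracle_saboteur_registry():
    from lakeq.predictors import ModelRegistry

    return ModelRegistry([
        TruthOracle("oracle"),
        TruthOracle("saboteur", bias=10.0),
    ])
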