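"""Forecast error metrics: MAE, RMSE and MAPE (percent).

For multichannel inputs each metric is computed per channel and the pooled
value is the equal-weight mean over channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["mae", "rmse", "mape", "MetricReport", "evaluate"]

MAPE_FLOOR = 1e-8


def _check(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape}, pred {pred.shape}")
    if truth.ndim == 1:
        truth, pred = truth[:, None], pred[:, None]
    return truth, pred


def _pool(per_channel: np.ndarray, pooled: bool):
    return float(per_channel.mean()) if pooled else per_channel


def mae(truth, pred, pooled: bool = True):
    """Mean absolute error; pooled = equal-weight mean over channels."""
    truth, pred = _check(truth, pred)
    return _pool(np.abs(pred - truth).mean(axis=0), pooled)


def rmse(truth, pred, pooled: bool = True):
    """Root mean squared error per channel, pooled by equal-weight mean."""
    truth, pred = _check(truth, pred)
    return _pool(np.sqrt(((pred - truth) ** 2).mean(axis=0)), pooled)


def mape(truth, pred, pooled: bool = True, mask_small: bool = False,
         floor: float = MAPE_FLOOR):
    """Mean absolute percentage error, in percent.

    Truth values with |q| below ``floor`` make the ratio meaningless; they
    raise unless ``mask_small`` drops them from the average.
    """
    truth, pred = _check(truth, pred)
    small = np.abs(truth) < floor
    if small.any() and not mask_small:
        raise ValueError(
            f"{int(small.sum())} truth value(s) below {floor}; MAPE undefined "
            "(pass mask_small=True to exclude them)"
        )
    ratio = np.abs((pred - truth) / np.where(small, np.nan, truth))
    with np.errstate(invalid="ignore"):
        per_channel = 100.0 * np.nanmean(ratio, axis=0)
    return _pool(per_channel, pooled)


@dataclass
class MetricReport:
    """Per-channel and pooled MAE / RMSE / MAPE for one forecast."""

    mae: float
    rmse: float
    mape: float
    mae_per_channel: np.ndarray
    rmse_per_channel: np.ndarray
    mape_per_channel: np.ndarray
    channel_names: list[str]

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "MAE": self.mae_per_channel,
                "RMSE": self.rmse_per_channel,
                "MAPE_pct": self.mape_per_channel,
            },
            index=self.channel_names,
        )
        frame.loc["pooled"] = [self.mae, self.rmse, self.mape]
        return frame


def evaluate(truth, pred, channel_names: list[str] | None = None,
             mask_small: bool = True) -> MetricReport:
    """Full metric report for a (steps x channels) truth/prediction pair."""
    truth2, pred2 = _check(truth, pred)
    names = channel_names or [f"ch{i + 1}" for i in range(truth2.shape[1])]
    return MetricReport(
        mae=mae(truth2, pred2),
        rmse=rmse(truth2, pred2),
        mape=mape(truth2, pred2, mask_small=mask_small),
        mae_per_channel=mae(truth2, pred2, pooled=False),
        rmse_per_channel=rmse(truth2, pred2, pooled=False),
        mape_per_channel=mape(truth2, pred2, pooled=False, mask_small=mask_small),
        channel_names=names,
    )
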