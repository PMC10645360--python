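"""Time-ordered multichannel series container.

``SeriesMatrix`` is the exchange type used by every stage of the package: a
dense v-by-s matrix of indicator concentrations on a uniform time grid with
named channels.  It deliberately stays thin — a validated wrapper around a
numpy array plus a :class:`pandas.DatetimeIndex` — and converts losslessly to
and from a :class:`pandas.DataFrame` for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SeriesMatrix"]


@dataclass
class SeriesMatrix:
    """A uniformly sampled multivariate series.

    Parameters
    ----------
    timestamps
        Strictly increasing, uniformly spaced time points (length v >= 2).
    values
        Array of shape (v, s); one column per indicator channel.
    channel_names
        s channel labels, unique.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        v, s = self.values.shape
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(s)]
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != s:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {s} columns"
            )
        if len(set(self.channel_names)) != s:
            raise ValueError("channel names must be unique")
        if v < 2:
            raise ValueError("series needs at least 2 rows")
        if len(self.timestamps) != v:
            raise ValueError("timestamps and values disagree on length")
        deltas = np.diff(self.timestamps.asi8)
        if not (deltas > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(set(deltas)) > 1:
            raise ValueError("timestamps must be uniformly spaced")
        if not np.isfinite(self.values).all():
            raise ValueError(
                "series contains missing or non-finite values; "
                "read with interpolate_missing=True to impute linearly"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def step(self) -> pd.Timedelta:
        """The (uniform) sampling interval."""
        return self.timestamps[1] - self.timestamps[0]

    def slice(self, start: int, stop: int) -> "SeriesMatrix":
        """Row slice [start, stop) as a new SeriesMatrix."""
        return SeriesMatrix(
            self.timestamps[start:stop],
            self.values[start:stop].copy(),
            list(self.channel_names),
        )

    def with_values(self, values: np.ndarray) -> "SeriesMatrix":
        """Same grid and channels, new values (same shape)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the shape")
        return SeriesMatrix(self.timestamps, values, list(self.channel_names))

    # -- conversion / I/O ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.timestamps, columns=self.channel_names
        ).rename_axis("timestamp")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SeriesMatrix":
        return cls(
            pd.DatetimeIndex(frame.index),
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    @classmethod
    def read_csv(cls, path, interpolate_missing: bool = False) -> "SeriesMatrix":
        """Load a CSV whose first column is an ISO-8601 timestamp.

        Missing entries are rejected unless ``interpolate_missing`` asks for
        linear interpolation along time (edge gaps are filled by the nearest
        observed value).
        """
        frame = pd.read_csv(path, index_col=0, parse_dates=True)
        if frame.isna().any().any():
            if not interpolate_missing:
                bad = [c for c in frame.columns if frame[c].isna().any()]
                raise ValueError(
                    f"missing values in channel(s) {bad}; pass "
                    "interpolate_missing=True to impute linearly"
                )
            frame = frame.interpolate(method="linear", limit_direction="both")
        return cls.from_frame(frame)
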