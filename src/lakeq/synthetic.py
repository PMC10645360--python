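"""Synthetic water-quality series generators.

The study data these generators emulate are hourly multivariate indicator
concentrations: a dozen correlated channels (nutrients, organics, physical
indices) sampled every hour for six weeks (1008 steps), driven by shared
diurnal and multi-week cycles, contaminated by additive Gaussian sensor
noise, and punctuated by abrupt level shifts after weather events.

``generate`` builds such a series from shared latent factors times a loading
matrix plus channel noise and scheduled jumps, optionally returning a
ground-truth sidecar (factors, noiseless values, jump schedule) for tests.
``generate_regime_benchmark`` builds a two-regime series in which a
different base forecaster is best in each regime — near-linear trend
segments (autoregression-friendly) alternating with plateau/level-shift
segments (persistence-friendly) — to exercise model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import SeriesMatrix

__all__ = [
    "DEFAULT_CHANNELS",
    "SyntheticSpec",
    "RegimeSpec",
    "generate",
    "generate_regime_benchmark",
]

# Typical magnitudes for the twelve indicators the method targets
# (mg/L except chroma/turbidity in index units, conductivity in uS/cm,
# Chl-a in ug/L).
DEFAULT_CHANNELS: dict[str, tuple[float, float]] = {
    "KMnO4": (6.0, 0.8),
    "COD": (20.0, 2.5),
    "BOD5": (4.0, 0.6),
    "TOC": (8.0, 1.0),
    "NH3-N": (0.5, 0.08),
    "chroma": (15.0, 2.0),
    "conductivity": (600.0, 40.0),
    "TDS": (300.0, 20.0),
    "turbidity": (10.0, 1.5),
    "NO3-N": (2.0, 0.3),
    "Chl-a": (30.0, 6.0),
    "fluoride": (0.4, 0.05),
}

_N_FACTORS = 3  # diurnal cycle, multi-week trend, slow stochastic drift


def _default_loadings(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Loading matrix giving a dominant shared factor plus two weaker ones.

    Roughly two thirds of the channels load heavily on the diurnal factor so
    the leading correlation eigenvalue is well above 2 at default noise.
    """
    loadings = np.zeros((n_channels, _N_FACTORS))
    for i in range(n_channels):
        if i % 3 != 2:
            loadings[i] = (0.9, 0.3, 0.2)
        else:
            loadings[i] = (0.2, 0.8, 0.4)
        if i % 4 == 1:
            loadings[i, 0] *= -1  # some indicators move against the cycle
    loadings += 0.05 * rng.standard_normal(loadings.shape)
    return loadings


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic indicator series.

    ``changepoints`` is a list of (step, channel_index, jump) triples: from
    ``step`` (1-based, inclusive) onward the channel level shifts by ``jump``
    in units of that channel's amplitude.
    """

    n_channels: int = 12
    n_steps: int = 1008
    start: str = "2021-07-26 00:00"
    freq: str = "h"
    base_levels: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    loadings: np.ndarray | None = None
    noise_scale: float = 0.3     # channel noise sd as a fraction of amplitude
    # None -> abrupt level shifts at 40% and 70% of the series on a few
    # channels; [] disables them
    changepoints: list[tuple[int, int, float]] | None = None
    seed: int = 0

    def resolved_changepoints(self) -> list[tuple[int, int, float]]:
        if self.changepoints is not None:
            return list(self.changepoints)
        early, late = max(1, int(0.4 * self.n_steps)), max(1, int(0.7 * self.n_steps))
        chans = [10 % self.n_channels, 4 % self.n_channels, 8 % self.n_channels]
        return [(early, chans[0], 2.0), (late, chans[1], -1.5),
                (late, chans[2], 2.5)]

    def resolve(self, rng: np.random.Generator):
        names = list(DEFAULT_CHANNELS)
        if self.n_channels <= len(names):
            names = names[: self.n_channels]
        else:
            names += [f"aux{i}" for i in range(self.n_channels - len(names))]
        defaults = [DEFAULT_CHANNELS.get(n, (10.0, 1.5)) for n in names]
        base = (
            np.asarray(self.base_levels, dtype=float)
            if self.base_levels is not None
            else np.array([b for b, _ in defaults])
        )
        amp = (
            np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes is not None
            else np.array([a for _, a in defaults])
        )
        loadings = (
            np.asarray(self.loadings, dtype=float)
            if self.loadings is not None
            else _default_loadings(self.n_channels, rng)
        )
        return names, base, amp, loadings


@dataclass
class GenerationTruth:
    """Ground-truth sidecar: what the generator actually drew."""

    factors: np.ndarray          # n_steps x n_factors
    noiseless: np.ndarray        # n_steps x n_channels, before noise/clipping
    noise_sd: np.ndarray         # per-channel noise standard deviation
    changepoints: list[tuple[int, int, float]]
    clipped_fraction: float

    def write_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "factors": self.factors.tolist(),
                    "noiseless": self.noiseless.tolist(),
                    "noise_sd": self.noise_sd.tolist(),
                    "changepoints": [list(c) for c in self.changepoints],
                    "clipped_fraction": self.clipped_fraction,
                }
            )
        )


def _latent_factors(n_steps: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_steps)
    diurnal = np.sin(2 * np.pi * t / 24.0 + rng.uniform(0, 2 * np.pi))
    weekly = np.sin(2 * np.pi * t / 504.0 + rng.uniform(0, 2 * np.pi))
    drift = np.empty(n_steps)
    drift[0] = rng.standard_normal()
    innovation_sd = np.sqrt(1 - 0.98**2)  # stationary unit variance
    for i in range(1, n_steps):
        drift[i] = 0.98 * drift[i - 1] + innovation_sd * rng.standard_normal()
    return np.column_stack([diurnal, weekly, drift])


def generate(
    spec: SyntheticSpec | None = None, return_truth: bool = False
):
    """Draw one synthetic indicator series from the spec.

    Returns the SeriesMatrix, or (SeriesMatrix, GenerationTruth) when
    ``return_truth`` is set.  Negative values are clipped at zero (with a
    warning) since concentrations are nonnegative.
    """
    spec = spec or SyntheticSpec()
    changepoints = spec.resolved_changepoints()
    for step, chan, _ in changepoints:
        if not 1 <= step <= spec.n_steps:
            raise ValueError(f"changepoint step {step} outside [1, {spec.n_steps}]")
        if not 0 <= chan < spec.n_channels:
            raise ValueError(f"changepoint channel {chan} out of range")
    rng = np.random.default_rng(spec.seed)
    names, base, amp, loadings = spec.resolve(rng)
    factors = _latent_factors(spec.n_steps, rng)

    noiseless = base + amp * (factors @ loadings.T)
    for step, chan, jump in changepoints:
        noiseless[step - 1 :, chan] += jump * amp[chan]

    noise_sd = spec.noise_scale * amp
    values = noiseless + noise_sd * rng.standard_normal(noiseless.shape)

    clipped = values < 0
    if clipped.any():
        warnings.warn(
            f"clipped {clipped.sum()} negative value(s) at zero "
            "(concentrations are nonnegative)",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)

    series = SeriesMatrix(
        pd.date_range(spec.start, periods=spec.n_steps, freq=spec.freq),
        values,
        names,
    )
    if not return_truth:
        return series
    truth = GenerationTruth(
        factors=factors,
        noiseless=noiseless,
        noise_sd=noise_sd,
        changepoints=changepoints,
        clipped_fraction=float(clipped.mean()),
    )
    return series, truth


@dataclass
class RegimeSpec:
    """Recipe for the regime-switching benchmark series.

    Regimes follow ``pattern`` in blocks of ``block_length`` steps.  "trend"
    blocks are near-linear ramps buried in heavy measurement noise — the
    territory of a fitted linear autoregression, which both averages the
    noise and extrapolates the slope, while persistence pays sqrt(2) times
    the noise and a window mean lags the ramp by half a window.  "plateau"
    blocks are quiet levels with occasional per-channel shifts — persistence
    territory, since an averaging model smears every shift across its whole
    window.  The default pattern weights trends 2:1 so the overall best
    single model is well separated, while each regime still has a different
    winner.
    """

    n_channels: int = 12
    n_steps: int = 1008
    block_length: int = 96
    pattern: tuple[str, ...] = ("trend", "plateau", "trend")
    trend_slope: float = 0.25      # per-step drift, in channel-scale units
    trend_noise: float = 0.8       # noise sd within trend blocks
    plateau_jump: float = 2.0      # level-shift magnitude within plateaus
    jump_every: int = 8            # mean steps between shifts, per channel
    plateau_noise: float = 0.05    # noise sd within plateau blocks
    center: float = 10.0           # long-run latent level
    revert_p: float = 0.85         # probability a trend points back to center
    start: str = "2021-07-26 00:00"
    freq: str = "h"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ValueError("need at least one regime in the pattern")
        for r in self.pattern:
            if r not in ("trend", "plateau"):
                raise ValueError(f"unknown regime kind '{r}'")


#: label values in the returned regime-label array
REGIME_LABELS = {"trend": 0, "plateau": 1}


def generate_regime_benchmark(
    spec: RegimeSpec | None = None,
) -> tuple[SeriesMatrix, np.ndarray]:
    """Build the regime-switching series and its per-step regime labels.

    Labels are 0 for trend steps and 1 for plateau steps.  With a
    single-kind pattern the output is a homogeneous series of that kind.
    """
    spec = spec or RegimeSpec()
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_steps, spec.n_channels

    scales = 1.0 + 0.5 * rng.random(s)
    offsets = 5.0 * rng.random(s)
    level = np.full(s, spec.center)
    latent = np.empty((n, s))
    labels = np.empty(n, dtype=int)
    pos = 0
    block_idx = 0
    while pos < n:
        kind = spec.pattern[block_idx % len(spec.pattern)]
        end = min(pos + spec.block_length, n)
        labels[pos:end] = REGIME_LABELS[kind]
        if kind == "trend":
            # slopes revert toward the long-run center so levels stay inside
            # the range the models are trained on
            toward = -1.0 if (level - spec.center).mean() > 0 else 1.0
            sign = toward if rng.random() < spec.revert_p else -toward
            slope = spec.trend_slope * sign * rng.uniform(0.6, 1.4)
            for t in range(pos, end):
                level = level + slope
                latent[t] = level + spec.trend_noise * rng.standard_normal(s)
        else:
            for t in range(pos, end):
                hits = rng.random(s) < 1.0 / spec.jump_every
                if hits.any():
                    sign = np.where(rng.random(s) < 0.5, 1.0, -1.0)
                    level = level + hits * spec.plateau_jump * sign
                latent[t] = level + spec.plateau_noise * rng.standard_normal(s)
        pos = end
        block_idx += 1

    values = offsets + scales * latent
    names = list(DEFAULT_CHANNELS)[:s] if s <= 12 else [f"ch{i+1}" for i in range(s)]
    series = SeriesMatrix(
        pd.date_range(spec.start, periods=n, freq=spec.freq), values, names
    )
    return series, labels
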