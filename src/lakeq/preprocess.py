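"""Denoising and correlation-structure diagnostics for indicator series.

Two stages run before any forecasting:

* **Recursive average filtering (RAF)** — trailing-window moving-average
  smoothing obtained by convolving each channel with a uniform kernel of
  length ``l``.  The first ``l - 1`` output entries are the ramp-in partial
  sums (N_1 + ... + N_j) / l, so output length equals input length; a mask
  marks those attenuated positions so downstream code may discard them.

* **Correlation PCA** — eigendecomposition of the s-by-s correlation matrix
  of the z-scored channels, reporting per-component variance-interpretation
  (contribution) rates, cumulative rates, SPSS-convention loadings
  (eigenvector times sqrt(eigenvalue), sign-flipped so the dominant loading
  of each component is positive), communalities, and the retained component
  count under the cumulative >= threshold rule (default 85%).  KMO
  sampling-adequacy and Bartlett sphericity statistics are provided as
  suitability diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import SeriesMatrix

__all__ = [
    "SmootherConfig",
    "PCAReport",
    "recursive_average_filter",
    "ramp_in_mask",
    "column_normalize",
    "fit_pca",
    "communalities",
    "select_n_components",
    "kmo_and_bartlett",
]


@dataclass(frozen=True)
class SmootherConfig:
    """Uniform-kernel smoother settings; larger windows smooth harder."""

    window_length: int = 5

    def __post_init__(self) -> None:
        if int(self.window_length) != self.window_length or self.window_length < 1:
            raise ValueError("window_length must be a positive integer")


def recursive_average_filter(
    series: SeriesMatrix, cfg: SmootherConfig | int = SmootherConfig()
) -> SeriesMatrix:
    """Smooth every channel with a trailing uniform window of length l.

    Entry j (1-based) is (N_{j-l+1} + ... + N_j)/l for j >= l and the
    ramp-in partial sum (N_1 + ... + N_j)/l for j < l, i.e. the leading
    n terms of the full convolution of the channel with (1/l, ..., 1/l).
    """
    if isinstance(cfg, int):
        cfg = SmootherConfig(cfg)
    l = cfg.window_length
    n = series.n_steps
    if l > n:
        raise ValueError(f"window_length {l} exceeds series length {n}")
    kernel = np.full(l, 1.0 / l)
    out = np.empty_like(series.values)
    for k in range(series.n_channels):
        out[:, k] = np.convolve(series.values[:, k], kernel)[:n]
    return series.with_values(out)


def ramp_in_mask(n_steps: int, window_length: int) -> np.ndarray:
    """Boolean mask, True at the attenuated ramp-in positions (< l - 1)."""
    mask = np.zeros(n_steps, dtype=bool)
    mask[: window_length - 1] = True
    return mask


def column_normalize(series: SeriesMatrix) -> SeriesMatrix:
    """Scale each channel to unit Euclidean norm (no centering)."""
    norms = np.sqrt((series.values**2).sum(axis=0))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [series.channel_names[i] for i in zero]
        raise ValueError(f"cannot normalize all-zero channel(s): {names}")
    return series.with_values(series.values / norms)


def communalities(loadings: np.ndarray) -> np.ndarray:
    """Per-indicator sum of squared loadings over the retained components.

    The communality (common degree) of indicator i is sum_k m_ik^2 — the
    share of its variance the retained components explain.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim == 1:
        loadings = loadings[None, :]
    if loadings.shape[1] < 1:
        raise ValueError("need at least one component")
    return (loadings**2).sum(axis=1)


def select_n_components(
    contribution_rates: np.ndarray, retention_threshold: float = 85.0
) -> int:
    """Smallest p whose cumulative contribution rate reaches the threshold.

    ``contribution_rates`` are per-component percentages in descending
    component order (they need not be sorted by magnitude).
    """
    if not 0 < retention_threshold <= 100:
        raise ValueError("retention_threshold must be in (0, 100]")
    cum = np.cumsum(np.asarray(contribution_rates, dtype=float))
    hit = np.flatnonzero(cum >= retention_threshold - 1e-9)
    if hit.size == 0:
        return len(cum)
    return int(hit[0]) + 1


@dataclass
class PCAReport:
    """Correlation-PCA summary: spectrum, loadings, retention, suitability."""

    eigenvalues: np.ndarray          # s, descending
    contribution_rates: np.ndarray   # s, percent, sums to 100
    cumulative_rates: np.ndarray     # s, percent, nondecreasing
    loadings: np.ndarray             # s x p, SPSS component-matrix convention
    communalities: np.ndarray        # s, from the retained loadings
    n_components: int
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    channel_names: list[str]
    all_loadings: np.ndarray         # s x s, every component

    def eigen_table(self):
        """Eigenvalue / VIR / SVIR table, one row per component."""
        import pandas as pd

        return pd.DataFrame(
            {
                "eigenvalue": np.round(self.eigenvalues, 3),
                "VIR_pct": np.round(self.contribution_rates, 3),
                "SVIR_pct": np.round(self.cumulative_rates, 3),
            },
            index=pd.RangeIndex(1, len(self.eigenvalues) + 1, name="component"),
        )

    def loading_table(self):
        """Retained-component loadings with a communality (CD) column."""
        import pandas as pd

        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        frame = pd.DataFrame(
            np.round(self.loadings, 3), index=self.channel_names, columns=cols
        )
        frame["CD"] = np.round(self.communalities, 3)
        return frame

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "contribution_rates_pct": self.contribution_rates.tolist(),
            "cumulative_rates_pct": self.cumulative_rates.tolist(),
            "loadings": self.loadings.tolist(),
            "communalities": self.communalities.tolist(),
            "n_components": self.n_components,
            "kmo": self.kmo,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
            "channel_names": self.channel_names,
        }


def _correlation_matrix(series: SeriesMatrix) -> np.ndarray:
    values = series.values
    if not np.isfinite(values).all():
        raise ValueError("series contains non-finite values")
    sd = values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [series.channel_names[i] for i in dead]
        raise ValueError(f"constant channel(s) have zero variance: {names}")
    return np.corrcoef(values, rowvar=False)


def fit_pca(series: SeriesMatrix, retention_threshold: float = 85.0) -> PCAReport:
    """Correlation-matrix PCA with the cumulative-contribution retention rule.

    Retains the smallest p components whose cumulative variance-interpretation
    rate reaches ``retention_threshold`` percent.
    """
    if not 0 < retention_threshold <= 100:
        raise ValueError("retention_threshold must be in (0, 100]")
    v, s = series.values.shape
    if v <= s:
        warnings.warn(
            f"only {v} samples for {s} channels; the correlation matrix is "
            "rank-deficient and the spectrum unreliable",
            stacklevel=2,
        )
    corr = _correlation_matrix(series)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    rates = 100.0 * eigval / eigval.sum()
    cum = np.cumsum(rates)
    p = select_n_components(rates, retention_threshold)

    # SPSS component-matrix convention: loading = eigenvector * sqrt(lambda),
    # each component flipped so its largest-magnitude entry is positive.
    all_loadings = eigvec * np.sqrt(eigval)
    for k in range(s):
        col = all_loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            all_loadings[:, k] = -col
    loadings = all_loadings[:, :p]

    try:
        kmo, chi2, df, pval = kmo_and_bartlett(series)
    except ValueError:
        # singular correlation matrix (e.g. fewer samples than channels):
        # the spectrum is still reportable, the suitability tests are not
        kmo, chi2, pval = float("nan"), float("nan"), float("nan")
        df = s * (s - 1) // 2
    return PCAReport(
        eigenvalues=eigval,
        contribution_rates=rates,
        cumulative_rates=cum,
        loadings=loadings,
        communalities=communalities(loadings),
        n_components=p,
        kmo=kmo,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        channel_names=list(series.channel_names),
        all_loadings=all_loadings,
    )


def kmo_and_bartlett(series: SeriesMatrix) -> tuple[float, float, int, float]:
    """Kaiser–Meyer–Olkin sampling adequacy and Bartlett's sphericity test.

    KMO compares squared correlations against squared anti-image partial
    correlations; values above 0.5 are conventionally adequate for PCA.
    Bartlett tests the identity-correlation null via
    chi2 = -((v - 1) - (2 s + 5) / 6) * ln det(R) on s (s - 1) / 2 df.
    """
    corr = _correlation_matrix(series)
    v, s = series.values.shape

    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix; KMO/Bartlett undefined")
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - slogdet guards
        raise ValueError("singular correlation matrix") from exc
    diag = np.diag(inv)
    if not (np.isfinite(diag).all() and (diag > 0).all()):
        raise ValueError("singular correlation matrix; KMO/Bartlett undefined")

    d = 1.0 / np.sqrt(diag)
    partial = -inv * np.outer(d, d)
    off = ~np.eye(s, dtype=bool)
    r2 = (corr[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    kmo = float(r2 / (r2 + p2))

    chi2 = float(-((v - 1) - (2 * s + 5) / 6.0) * logdet)
    df = s * (s - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return kmo, chi2, df, pval
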