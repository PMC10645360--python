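"""Dual-stage orchestration: learn to pick models, then learn the errors.

Stage 1 trains a triple-Q agent that, at each step of the training series,
selects one base forecaster, scores it by the multi-indicator mean reward
against the truth, and updates its tables.  A deterministic greedy pass then
produces the preliminary prediction series and its error series
(truth - preliminary).  Stage 2 re-initializes the agent and repeats the
whole procedure on the error series with its own model set.  At prediction
time the stage-2 agent forecasts the next error and that corrected error is
added to the preliminary forecast (compensation).

Because the base models are fitted once and training walks the true series,
each model's one-step forecast at a given step is the same in every episode;
forecasts and per-(action, step) rewards are therefore precomputed once and
the episode loop reduces to pure table updates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .predictors import ModelRegistry, make_model
from .qcore import ArctanSchedule, TripleQState, greedy_policy, select_action, update
from .series import SeriesMatrix

__all__ = [
    "EpisodeTrace",
    "StageResult",
    "DDForecaster",
    "train_stage",
    "greedy_pass",
    "run_dd",
    "predict",
    "evaluate_one_step",
]


@dataclass
class EpisodeTrace:
    """Per-step record of one training episode.

    Preliminary predictions and errors are reconstructed on demand from the
    stage's forecast cache (forecasts depend only on the step and the chosen
    model, not on the episode).
    """

    u: int                      # episode index, 1-based
    t_index: np.ndarray         # absolute row indices of the predicted steps
    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    eps: float
    _forecasts: np.ndarray = field(repr=False)   # (K, T, s) cache
    _truth: np.ndarray = field(repr=False)       # (T, s)

    def __len__(self) -> int:
        return len(self.t_index)

    def predictions(self) -> np.ndarray:
        return self._forecasts[self.actions, np.arange(len(self))]

    def errors(self) -> np.ndarray:
        return self._truth - self.predictions()

    def to_records(self) -> list[dict]:
        return [
            {
                "episode": self.u,
                "step": int(t),
                "state": int(s),
                "action": int(a),
                "reward": float(r),
                "eps": self.eps,
            }
            for t, s, a, r in zip(self.t_index, self.states, self.actions, self.rewards)
        ]


@dataclass
class StageResult:
    """Trained tables, traces and caches for one learning stage."""

    q: TripleQState
    traces: list[EpisodeTrace]
    episodes_run: int
    last_policy_change: int
    forecasts: np.ndarray       # (K, T, s)
    t0: int                     # first predicted row index (= max window)
    channel_mean: np.ndarray
    channel_std: np.ndarray


def _reward_stats(values: np.ndarray, zscore: bool) -> tuple[np.ndarray, np.ndarray]:
    if not zscore:
        s = values.shape[1]
        return np.zeros(s), np.ones(s)
    mean = values.mean(axis=0)
    std = values.std(axis=0, ddof=0)
    std = np.where(std < 1e-12, 1.0, std)  # degenerate channels score raw
    return mean, std


def train_stage(
    series: SeriesMatrix,
    registry: ModelRegistry,
    schedule=None,
    n_episodes: int = 500,
    seed: int = 0,
    alpha: float = 0.1,
    gamma: float = 0.9,
    c: float = 1.0,
    patience: int | None = 50,
    reward_zscore: bool = True,
    keep_traces: bool = True,
    eval_start: int | None = None,
    refit_every: int | None = None,
) -> StageResult:
    """Train one triple-Q model-selection stage on a series.

    Each episode walks the series step by step: select a model under the
    episode's exploitation probability, forecast one step, score it by the
    mean reward on (z-scored) channels, and update the tables; the state at
    the next step is the model just chosen.  Early-stops once the greedy
    policy has been stable for ``patience`` consecutive episodes.

    With ``eval_start`` set, rewards are out of sample: models are fitted on
    the rows before ``eval_start`` and the walk covers the rows from there
    on, so fitted models are scored on data they did not see and the error
    series matches the deployed models' error distribution.  With
    ``refit_every`` also set, forecasts instead come from expanding-window
    refits every that many rows and the registry is refitted on the whole
    series afterwards (more data per fit, at the cost of an error series
    drawn from a mixture of fit sizes).  By default (``eval_start=None``)
    models are fitted once on the whole series and the walk starts after the
    largest model window.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    if len(registry) == 0:
        raise ValueError("cannot train with an empty model registry")
    schedule = schedule or ArctanSchedule()
    w = registry.max_window
    n = series.n_steps
    if n <= w + 1:
        raise ValueError(
            f"series length {n} too short for model window {w} (need > {w + 1})"
        )
    values = series.values
    K = len(registry)

    if eval_start is None:
        registry.fit_all(series)
        walk_start = w
        t_index = np.arange(walk_start, n)
        forecasts = np.empty((K, len(t_index), series.n_channels))
        for a, model in enumerate(registry):
            for i, t in enumerate(t_index):
                forecasts[a, i] = model.predict_at(values, t)
    else:
        if not w < eval_start < n - 1:
            raise ValueError(
                f"eval_start={eval_start} must leave room for the window "
                f"({w}) and at least two walked rows (series length {n})"
            )
        walk_start = eval_start
        t_index = np.arange(walk_start, n)
        forecasts = np.empty((K, len(t_index), series.n_channels))
        if refit_every is None:
            registry.fit_all(series.slice(0, eval_start))
            for a, model in enumerate(registry):
                for i, t in enumerate(t_index):
                    forecasts[a, i] = model.predict_at(values, t)
        else:
            if refit_every < 1:
                raise ValueError("refit_every must be >= 1")
            for block_start in range(eval_start, n, refit_every):
                block_end = min(block_start + refit_every, n)
                registry.fit_all(series.slice(0, block_start))
                for a, model in enumerate(registry):
                    for t in range(block_start, block_end):
                        forecasts[a, t - walk_start] = model.predict_at(values, t)
            registry.fit_all(series)  # deployment refit on everything

    T = len(t_index)
    mean, std = _reward_stats(values, reward_zscore)
    truth = values[walk_start:]
    # reward[a, i] = mean over channels of -|truth - forecast| / std
    rewards = -np.abs((truth[None, :, :] - forecasts) / std).mean(axis=2)

    q = TripleQState.zeros(K, K, alpha=alpha, gamma=gamma, c=c)
    rng = np.random.default_rng(seed)
    traces: list[EpisodeTrace] = []
    policy = greedy_policy(q)
    last_change, unchanged, episodes_run = 0, 0, 0

    for u in range(1, n_episodes + 1):
        eps = schedule(u)
        state = 0
        states = np.empty(T, dtype=int)
        actions = np.empty(T, dtype=int)
        step_rewards = np.empty(T)
        for i in range(T):
            a = select_action(q, state, eps, rng)
            r = rewards[a, i]
            update(q, state, a, r, a)   # next state = model just chosen
            states[i], actions[i], step_rewards[i] = state, a, r
            state = a
        if keep_traces:
            traces.append(
                EpisodeTrace(u, t_index, states, actions, step_rewards, eps,
                             forecasts, truth)
            )
        new_policy = greedy_policy(q)
        if np.array_equal(new_policy, policy):
            unchanged += 1
        else:
            unchanged, last_change = 0, u
        policy = new_policy
        episodes_run = u
        if patience is not None and unchanged >= patience:
            break

    return StageResult(
        q, traces, episodes_run, last_change, forecasts, walk_start, mean, std
    )


def greedy_pass(
    series: SeriesMatrix,
    registry: ModelRegistry,
    q: TripleQState,
    start_state: int = 0,
    t_start: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Deterministic walk of the series under the greedy policy.

    Returns (predictions, errors, step indices, chosen actions, final state);
    errors are truth - prediction, channel order preserved.  The walk starts
    at ``t_start`` (default: after the largest model window).
    """
    policy = greedy_policy(q)
    w = registry.max_window
    if t_start is None:
        t_start = w
    if t_start < w:
        raise ValueError(f"t_start={t_start} is inside the model window ({w})")
    values = series.values
    t_index = np.arange(t_start, series.n_steps)
    preds = np.empty((len(t_index), series.n_channels))
    actions = np.empty(len(t_index), dtype=int)
    state = start_state
    for i, t in enumerate(t_index):
        a = int(policy[state])
        preds[i] = registry[a].predict_at(values, t)
        actions[i] = a
        state = a
    errors = values[t_start:] - preds
    return preds, errors, t_index, actions, state


@dataclass
class DDForecaster:
    """Trained two-stage forecaster: model selection plus error compensation."""

    registry1: ModelRegistry
    q1: TripleQState
    registry2: ModelRegistry
    q2: TripleQState
    config: RunConfig
    stage1_episodes: int = 0
    stage2_episodes: int = 0

    @property
    def w1(self) -> int:
        return self.registry1.max_window

    @property
    def w2(self) -> int:
        return self.registry2.max_window

    @property
    def min_history(self) -> int:
        return self.w1 + self.w2

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        for stage, registry, q in [
            ("stage1", self.registry1, self.q1),
            ("stage2", self.registry2, self.q2),
        ]:
            d = directory / stage
            registry.save(d)
            q.save(d)
        meta = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "stage1_episodes": self.stage1_episodes,
            "stage2_episodes": self.stage2_episodes,
        }
        (directory / "forecaster.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "DDForecaster":
        directory = Path(directory)
        meta = json.loads((directory / "forecaster.json").read_text())
        return cls(
            registry1=ModelRegistry.load(directory / "stage1"),
            q1=TripleQState.load(directory / "stage1"),
            registry2=ModelRegistry.load(directory / "stage2"),
            q2=TripleQState.load(directory / "stage2"),
            config=RunConfig(**meta["config"]),
            stage1_episodes=meta["stage1_episodes"],
            stage2_episodes=meta["stage2_episodes"],
        )


def _build_registry(kinds: list[str], window: int) -> ModelRegistry:
    return ModelRegistry([make_model(k, window) for k in kinds])


def run_dd(series: SeriesMatrix, config: RunConfig | None = None) -> DDForecaster:
    """Train the full dual-stage forecaster on the training split.

    The input series is used as-is (smooth beforehand if desired).  Stage 1
    learns model selection on the first ``train_rows`` rows; a greedy pass
    over that split yields the error series on which stage 2 is trained with
    re-initialized tables and a fresh model set.
    """
    config = config or RunConfig()
    if series.n_steps < config.train_rows:
        raise ValueError(
            f"series has {series.n_steps} rows, fewer than train_rows="
            f"{config.train_rows}"
        )
    train = series.slice(0, config.train_rows)
    schedule = ArctanSchedule(config.eps_scale, config.eps_offset)

    registry1 = _build_registry(config.models, config.model_window)
    eval1 = config.resolved_eval_start(config.train_rows, config.model_window)
    stage1 = train_stage(
        train, registry1, schedule,
        n_episodes=config.n_episodes, seed=config.seed,
        alpha=config.alpha, gamma=config.gamma, c=config.c,
        patience=config.patience, reward_zscore=config.reward_zscore,
        keep_traces=False, eval_start=eval1, refit_every=config.refit_every,
    )

    # error series from the stage-1 (out-of-fold) forecast cache under the
    # greedy policy, so stage 2 learns the deployment error structure
    policy = greedy_policy(stage1.q)
    t_index = np.arange(stage1.t0, config.train_rows)
    truth = train.values[stage1.t0 :]
    errors = np.empty_like(truth)
    state = 0
    for i in range(len(t_index)):
        a = int(policy[state])
        errors[i] = truth[i] - stage1.forecasts[a, i]
        state = a
    if np.abs(errors).max() < 1e-12:
        warnings.warn(
            "stage-1 errors are all (near) zero; stage 2 will learn a null "
            "correction",
            stacklevel=2,
        )
    err_series = SeriesMatrix(
        train.timestamps[t_index], errors, list(series.channel_names)
    )

    registry2 = _build_registry(
        config.resolved_stage2_models, config.resolved_stage2_window
    )
    eval2 = config.resolved_eval_start(
        err_series.n_steps, config.resolved_stage2_window
    )
    stage2 = train_stage(
        err_series, registry2, schedule,
        n_episodes=config.n_episodes, seed=config.seed + 1,
        alpha=config.alpha, gamma=config.gamma, c=config.c,
        patience=config.patience, reward_zscore=config.reward_zscore,
        keep_traces=False, eval_start=eval2, refit_every=config.refit_every,
    )
    # stage 2 is the last stage: nothing downstream consumes its errors, so
    # refit the error models on the whole error series for deployment
    registry2.fit_all(err_series)

    return DDForecaster(
        registry1, stage1.q, registry2, stage2.q, config,
        stage1_episodes=stage1.episodes_run, stage2_episodes=stage2.episodes_run,
    )


def predict(
    dd: DDForecaster,
    history: SeriesMatrix,
    horizon: int,
    return_components: bool = False,
):
    """Roll the forecaster forward ``horizon`` steps past the history.

    Per step the stage-1 greedy policy picks a model for the preliminary
    forecast and the stage-2 greedy policy picks an error model; the final
    forecast is preliminary + corrected error.  Multi-step horizons feed the
    final forecasts (and predicted errors) back into the buffers.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    w1, w2 = dd.w1, dd.w2
    if history.n_steps < w1 + w2:
        raise ValueError(
            f"history has {history.n_steps} rows; need at least {w1 + w2}"
        )
    pol1, pol2 = greedy_policy(dd.q1), greedy_policy(dd.q2)

    # realized stage-1 errors over the last w2 history rows seed the buffer
    values = history.values
    err_buf: list[np.ndarray] = []
    state1 = 0
    for t in range(history.n_steps - w2, history.n_steps):
        a = int(pol1[state1])
        pred = dd.registry1[a].predict_at(values, t)
        err_buf.append(values[t] - pred)
        state1 = a
    err_values = np.array(err_buf)

    data_buf = values.copy()
    state2 = 0
    finals = np.empty((horizon, history.n_channels))
    prelims = np.empty_like(finals)
    corrections = np.empty_like(finals)
    for h in range(horizon):
        a1 = int(pol1[state1])
        prelim = dd.registry1[a1].predict_next(data_buf[-w1:])
        a2 = int(pol2[state2])
        correction = dd.registry2[a2].predict_next(err_values[-w2:])
        final = prelim + correction
        prelims[h], corrections[h], finals[h] = prelim, correction, final
        data_buf = np.vstack([data_buf, final])
        err_values = np.vstack([err_values, correction])
        state1, state2 = a1, a2

    step = history.step
    timestamps = pd.date_range(
        history.timestamps[-1] + step, periods=horizon, freq=step
    )
    out = SeriesMatrix(timestamps, finals, list(history.channel_names))
    if not return_components:
        return out
    return out, out.with_values(prelims), out.with_values(corrections)


def evaluate_one_step(
    dd: DDForecaster, series: SeriesMatrix, t_start: int, t_end: int
) -> dict:
    """One-step-ahead evaluation over rows [t_start, t_end) with true history.

    At each step the preliminary forecast comes from the stage-1 greedy
    choice given the true trailing history; the compensation comes from the
    stage-2 greedy choice applied to the *realized* errors of the already
    observed steps, so the correction for step t uses only information from
    steps before t.  Returns truth, preliminary and final predictions plus
    the per-step model choices of both stages.
    """
    w1, w2 = dd.w1, dd.w2
    warmup = t_start - w2
    if warmup < w1:
        raise ValueError(
            f"t_start={t_start} leaves no room for warmup (need >= {w1 + w2})"
        )
    if not t_start < t_end <= series.n_steps:
        raise ValueError("need t_start < t_end <= series length")
    pol1, pol2 = greedy_policy(dd.q1), greedy_policy(dd.q2)
    values = series.values

    err_hist: list[np.ndarray] = []
    state1 = state2 = 0
    rows = []
    prelims, finals, truths = [], [], []
    for t in range(warmup, t_end):
        a1 = int(pol1[state1])
        prelim = dd.registry1[a1].predict_at(values, t)
        recording = t >= t_start
        if recording:
            a2 = int(pol2[state2])
            correction = dd.registry2[a2].predict_next(np.array(err_hist[-w2:]))
            final = prelim + correction
            prelims.append(prelim)
            finals.append(final)
            truths.append(values[t])
            rows.append(
                {
                    "timestamp": series.timestamps[t],
                    "stage1_model": dd.registry1[a1].name,
                    "stage2_model": dd.registry2[a2].name,
                }
            )
            state2 = a2
        err_hist.append(values[t] - prelim)
        state1 = a1

    return {
        "t_index": np.arange(t_start, t_end),
        "truth": np.array(truths),
        "preliminary": np.array(prelims),
        "final": np.array(finals),
        "choices": pd.DataFrame(rows),
    }
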