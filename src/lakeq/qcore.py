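"""Tabular triple-Q learning engine.

The agent chooses, at each time step, which base forecasting model to apply.
States and actions both index the registered model set (the state at t+1 is
the model chosen at t), so the Q tables are W-by-K with W = K.

Three Q estimates are maintained to curb the optimism of the single max
operator.  After each transition all three tables are moved toward their own
bootstrapped targets from the shared combined table, and the combined value
for the touched cell is rebuilt as a convex combination of the cellwise mean
and minimum of the three estimates:

    lambda = |Q_ave - Q_min| / (c + |Q_ave - Q_min|),
    Q*     = lambda * Q_ave + (1 - lambda) * Q_min.

When the three estimates agree, lambda = 0 and Q* collapses to the common
value; the more they disagree, the more weight shifts from the pessimistic
minimum toward the mean.

Exploitation probability follows an increasing arctangent schedule of the
episode index, eps(u) = (2/pi) * arctan(scale * (u - offset)): early episodes
explore heavily, later ones exploit the learned table almost always.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ArctanSchedule",
    "ConstantSchedule",
    "mean_reward",
    "TripleQState",
    "select_action",
    "update",
    "greedy_policy",
    "learn_mdp",
    "MDPResult",
]


@dataclass(frozen=True)
class ArctanSchedule:
    """eps(u) = (2/pi) * arctan(scale * (u - offset)), clipped to [0, 1).

    Strictly increasing in the episode index u >= 1 with asymptote 1, so the
    agent explores widely at first and settles into exploitation.
    """

    scale: float = 0.2
    offset: float = 0.1

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def __call__(self, u: int) -> float:
        if u < 1:
            raise ValueError(f"episode index must be >= 1, got {u}")
        eps = (2.0 / np.pi) * np.arctan(self.scale * (u - self.offset))
        return float(np.clip(eps, 0.0, np.nextafter(1.0, 0.0)))


@dataclass(frozen=True)
class ConstantSchedule:
    """Fixed exploitation probability, the classical eps-greedy baseline."""

    eps: float = 0.5

    def __call__(self, u: int) -> float:
        if u < 1:
            raise ValueError(f"episode index must be >= 1, got {u}")
        return float(self.eps)


def mean_reward(truth: np.ndarray, prediction: np.ndarray) -> float:
    """Multi-indicator mean reward: average of -|y_t - y_p| over channels.

    Always <= 0, and 0 exactly when the prediction matches the truth on
    every indicator.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    prediction = np.asarray(prediction, dtype=float).ravel()
    if truth.shape != prediction.shape:
        raise ValueError(
            f"truth has {truth.size} indicators, prediction {prediction.size}"
        )
    return float(-np.abs(truth - prediction).mean())


@dataclass
class TripleQState:
    """Three Q tables plus their combined table over (state, action) cells."""

    q1: np.ndarray
    q2: np.ndarray
    q3: np.ndarray
    q_star: np.ndarray
    alpha: float = 0.1
    gamma: float = 0.9
    c: float = 1.0

    @classmethod
    def zeros(
        cls,
        n_states: int,
        n_actions: int,
        alpha: float = 0.1,
        gamma: float = 0.9,
        c: float = 1.0,
    ) -> "TripleQState":
        if n_states < 1 or n_actions < 1:
            raise ValueError("need at least one state and one action")
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= gamma < 1:
            raise ValueError("gamma must be in [0, 1)")
        if c <= 0:
            raise ValueError("c must be positive")
        shape = (n_states, n_actions)
        return cls(
            np.zeros(shape), np.zeros(shape), np.zeros(shape), np.zeros(shape),
            alpha=alpha, gamma=gamma, c=c,
        )

    @property
    def n_states(self) -> int:
        return self.q_star.shape[0]

    @property
    def n_actions(self) -> int:
        return self.q_star.shape[1]

    @property
    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.q1, self.q2, self.q3

    def copy(self) -> "TripleQState":
        return TripleQState(
            self.q1.copy(), self.q2.copy(), self.q3.copy(), self.q_star.copy(),
            alpha=self.alpha, gamma=self.gamma, c=self.c,
        )

    # -- serialization ---------------------------------------------------
    def save(self, directory) -> None:
        """One CSV per table plus a JSON of the scalar hyperparameters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in [
            ("q1", self.q1), ("q2", self.q2), ("q3", self.q3),
            ("q_star", self.q_star),
        ]:
            np.savetxt(directory / f"{name}.csv", table, delimiter=",")
        (directory / "qparams.json").write_text(
            json.dumps({"alpha": self.alpha, "gamma": self.gamma, "c": self.c})
        )

    @classmethod
    def load(cls, directory) -> "TripleQState":
        directory = Path(directory)
        params = json.loads((directory / "qparams.json").read_text())
        tables = {
            name: np.loadtxt(directory / f"{name}.csv", delimiter=",", ndmin=2)
            for name in ("q1", "q2", "q3", "q_star")
        }
        return cls(
            tables["q1"], tables["q2"], tables["q3"], tables["q_star"], **params
        )


def select_action(
    q: TripleQState, state: int, eps: float, rng: np.random.Generator
) -> int:
    """Epsilon-greedy draw: exploit argmax Q* with probability eps, else
    pick a uniformly random action.  Ties go to the lowest action index."""
    sigma = rng.random()
    if sigma > eps:
        return int(rng.integers(q.n_actions))
    return int(np.argmax(q.q_star[state]))


def update(
    q: TripleQState, state: int, action: int, reward: float, next_state: int
) -> TripleQState:
    """One triple-Q transition update, in place (the state is returned).

    All three targets use the pre-update combined value and each table's own
    next-state maximum; the combined cell is then rebuilt once from the
    mean/min weighting.
    """
    if not np.isfinite(reward):
        raise ValueError(f"non-finite reward {reward!r}")
    q_star_sa = q.q_star[state, action]
    targets = [
        reward + q.gamma * qi[next_state].max() for qi in q.tables
    ]
    for qi, target in zip(q.tables, targets):
        qi[state, action] = q_star_sa + q.alpha * (target - q_star_sa)
    cell = np.array([qi[state, action] for qi in q.tables])
    q_ave = cell.mean()
    q_min = cell.min()
    gap = abs(q_ave - q_min)
    lam = gap / (q.c + gap)
    q.q_star[state, action] = lam * q_ave + (1.0 - lam) * q_min
    return q


def greedy_policy(q: TripleQState) -> np.ndarray:
    """Per-state argmax of Q*, lowest action index on ties."""
    return np.argmax(q.q_star, axis=1)


@dataclass
class MDPResult:
    """Outcome of tabular learning on an explicit finite MDP."""

    q: TripleQState
    episodes_run: int
    last_policy_change: int   # last episode index at which the greedy policy changed (0 = never)
    policy_history: list[np.ndarray] = field(default_factory=list)


def learn_mdp(
    rewards: np.ndarray,
    transitions: np.ndarray,
    schedule,
    n_episodes: int,
    steps_per_episode: int,
    alpha: float = 0.1,
    gamma: float = 0.9,
    c: float = 1.0,
    seed: int = 0,
    start_state: int = 0,
    patience: int | None = None,
) -> MDPResult:
    """Train a triple-Q agent on a deterministic finite MDP.

    ``rewards`` and ``transitions`` are (n_states, n_actions) arrays giving
    the immediate reward and successor state of each (state, action) pair.
    Used for schedule/convergence experiments and as a harness for policy
    recovery checks.  ``patience`` stops early once the greedy policy has
    been unchanged for that many consecutive episodes.
    """
    rewards = np.asarray(rewards, dtype=float)
    transitions = np.asarray(transitions, dtype=int)
    n_states, n_actions = rewards.shape
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    q = TripleQState.zeros(n_states, n_actions, alpha=alpha, gamma=gamma, c=c)
    rng = np.random.default_rng(seed)
    policy = greedy_policy(q)
    last_change = 0
    unchanged = 0
    history: list[np.ndarray] = []
    episodes_run = 0
    for u in range(1, n_episodes + 1):
        eps = schedule(u)
        state = start_state
        for _ in range(steps_per_episode):
            action = select_action(q, state, eps, rng)
            update(q, state, action, rewards[state, action], transitions[state, action])
            state = transitions[state, action]
        new_policy = greedy_policy(q)
        history.append(new_policy)
        if np.array_equal(new_policy, policy):
            unchanged += 1
        else:
            unchanged = 0
            last_change = u
        policy = new_policy
        episodes_run = u
        if patience is not None and unchanged >= patience:
            break
    return MDPResult(q, episodes_run, last_change, history)
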