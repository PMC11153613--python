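"""Simulator for the emotion-yoked probabilistic reward-learning task.

Participants choose between two faces on each trial and learn, over 30-trial
blocks, which face pays off more often (60/40 contingencies). Emotional
blocks pair a happy and an angry expression of the same identity (option 1 =
happy); neutral blocks pair two neutral identities. The reward process is
identical across conditions — the conditions differ only through the
simulated agent's additive decision bias toward the happy face, which models
the prepotent emotional pull the task is designed to elicit.

Agents are forward runs of the double-update learner in :mod:`emolearn.rl`.
All randomness flows through ``numpy.random.Generator`` objects spawned from
a single integer seed, so simulated tables are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .rl import Q_INIT, QState, choice_probability, double_update  # noqa: F401

EMOTIONAL = "emotional"
NEUTRAL = "neutral"
HAPPY_OPTION = 1  # in emotional blocks option 1 is the happy face


@dataclass(frozen=True)
class TaskConfig:
    trials_per_block: int = 30
    blocks_per_condition: int = 2
    reward_contingencies: tuple[float, float] = (0.6, 0.4)

    def __post_init__(self) -> None:
        p_rich, p_lean = self.reward_contingencies
        if not (0.0 < p_rich < 1.0 and 0.0 < p_lean < 1.0):
            raise ValueError("reward contingencies must lie strictly inside (0, 1)")
        if abs(p_rich + p_lean - 1.0) > 1e-9:
            raise ValueError("reward contingencies must sum to 1")
        if self.trials_per_block < 1 or self.blocks_per_condition < 1:
            raise ValueError("trials_per_block and blocks_per_condition must be >= 1")

    @property
    def n_blocks(self) -> int:
        return 2 * self.blocks_per_condition

    @property
    def trials_per_visit(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant.

    ``happy_bias`` shifts the softmax toward option 1 in emotional blocks
    only; ``miss_rate`` is the per-trial probability of a missed response.
    """

    alpha: float
    beta: float
    happy_bias: float = 0.0
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError(f"miss_rate must be in [0, 1), got {self.miss_rate}")


def generate_reward_schedule(
    config: TaskConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent reward availability for both options, one block of trials.

    One option is designated rich (reward probability ``p_rich``), the other
    lean; each trial carries an independent Bernoulli availability draw per
    option, and the realised reward for a trial is the availability of the
    chosen option. Columns: ``trial`` (1-based), ``rich_option``,
    ``avail_opt1``, ``avail_opt2``.
    """
    p_rich, p_lean = config.reward_contingencies
    rich = int(rng.integers(1, 3))
    p1, p2 = (p_rich, p_lean) if rich == 1 else (p_lean, p_rich)
    n = config.trials_per_block
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "rich_option": rich,
            "avail_opt1": rng.random(n) < p1,
            "avail_opt2": rng.random(n) < p2,
        }
    )


def default_block_order(config: TaskConfig) -> list[str]:
    """Alternating emotional/neutral block order (order is configurable)."""
    return [EMOTIONAL, NEUTRAL] * config.blocks_per_condition


def simulate_agent(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
    block_order: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate one visit for one agent; returns a long trial table.

    The agent chooses by softmax over its Q values (plus ``happy_bias`` in
    emotional blocks), the chosen option's latent availability is paid out,
    and both Q values are double-updated. Q resets at every block start.
    Missing trials (rate ``miss_rate``) have no choice, no reward, no update.
    """
    order = block_order if block_order is not None else default_block_order(config)
    rows = []
    alpha = params.alpha
    for block_idx, condition in enumerate(order, start=1):
        schedule = generate_reward_schedule(config, rng)
        avail1 = schedule["avail_opt1"].to_numpy()
        avail2 = schedule["avail_opt2"].to_numpy()
        bias = params.happy_bias if condition == EMOTIONAL else 0.0
        q1, q2 = Q_INIT
        for t in range(config.trials_per_block):
            if rng.random() < params.miss_rate:
                rows.append((condition, block_idx, t + 1, 0, -1, True))
                continue
            x = params.beta * (q1 - q2) + bias
            p1 = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
            choice = 1 if rng.random() < p1 else 2
            reward = int(avail1[t] if choice == 1 else avail2[t])
            rows.append((condition, block_idx, t + 1, choice, reward, False))
            r = float(reward)
            if choice == 1:
                q1 += alpha * (r - q1)
                q2 += alpha * ((1.0 - r) - q2)
            else:
                q2 += alpha * (r - q2)
                q1 += alpha * ((1.0 - r) - q1)
    df = pd.DataFrame(
        rows, columns=["condition", "block", "trial", "choice", "reward", "missing"]
    )
    return df


#: Default group x visit agent parameters. Calibrated once so that the
#: simulated cohort reproduces the qualitative study pattern: responsive
#: agents learn above chance in every condition at both visits, while
#: resistant agents at the follow-up visit are pulled toward chance in the
#: emotional condition only (large happy-face bias, weaker value-guided
#: choice) yet still learn the neutral blocks.
DEFAULT_PARAM_MAP: dict[tuple[str, str], AgentParams] = {
    ("responsive", "A"): AgentParams(alpha=0.35, beta=5.5, happy_bias=0.32, miss_rate=0.03),
    ("responsive", "C"): AgentParams(alpha=0.38, beta=6.0, happy_bias=0.32, miss_rate=0.03),
    ("resistant", "A"): AgentParams(alpha=0.30, beta=4.5, happy_bias=0.32, miss_rate=0.03),
    ("resistant", "C"): AgentParams(alpha=0.20, beta=1.8, happy_bias=2.20, miss_rate=0.03),
}

#: Between-participant spread applied around the cell means (truncated draws).
BETWEEN_SUBJECT_SD = {"alpha": 0.08, "beta": 1.0, "happy_bias": 0.15}


def _draw_individual(
    cell: AgentParams, rng: np.random.Generator, sd: dict[str, float]
) -> AgentParams:
    alpha = float(np.clip(rng.normal(cell.alpha, sd["alpha"]), 0.02, 0.95))
    beta = float(np.clip(rng.normal(cell.beta, sd["beta"]), 0.2, 40.0))
    bias = float(rng.normal(cell.happy_bias, sd["happy_bias"]))
    return replace(cell, alpha=alpha, beta=beta, happy_bias=bias)


def simulate_visits(
    labels: pd.DataFrame,
    param_map: dict[tuple[str, str], AgentParams] | None = None,
    config: TaskConfig | None = None,
    seed: int = 0,
    visits: tuple[str, ...] = ("A", "C"),
    between_subject_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate the full cohort across visits.

    ``labels`` needs columns ``participant_id`` and ``label`` (group name);
    ``param_map`` must cover every (label, visit) cell. Individual agents get
    parameters drawn around their cell mean independently at each visit (set
    ``between_subject_sd`` to zeros for homogeneous agents), so between-visit
    change reflects the cell means.
    """
    param_map = DEFAULT_PARAM_MAP if param_map is None else param_map
    config = TaskConfig() if config is None else config
    sd = BETWEEN_SUBJECT_SD if between_subject_sd is None else between_subject_sd
    missing = [
        (g, v) for g in labels["label"].unique() for v in visits if (g, v) not in param_map
    ]
    if missing:
        raise KeyError(f"param_map missing cells: {missing}")
    root = np.random.SeedSequence(seed)
    tables = []
    for child, (_, row) in zip(
        root.spawn(len(labels)), labels.sort_values("participant_id").iterrows()
    ):
        rng = np.random.default_rng(child)
        for visit in visits:
            cell = param_map[(row["label"], visit)]
            params = _draw_individual(cell, rng, sd)
            df = simulate_agent(params, config, rng)
            df.insert(0, "participant_id", row["participant_id"])
            df.insert(1, "visit", visit)
            tables.append(df)
    return pd.concat(tables, ignore_index=True)
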