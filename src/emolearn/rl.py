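"""Double-update reinforcement-learning model of two-alternative reward learning.

The learner tracks the expected reward of both faces. On every non-missing
trial the chosen option's value moves toward the received outcome ``r`` and
the unchosen option's value moves toward the complementary outcome ``1 - r``,
with a single shared learning rate:

    Q_c  <- Q_c + alpha * (r - Q_c)
    Q_u  <- Q_u + alpha * ((1 - r) - Q_u)

reflecting the anticorrelated 60/40 reward structure of the task. Choices are
modelled by a softmax over the value difference with inverse temperature beta
(and, for simulation only, an additive decision bias toward the happy face).

A trial is an *ideal choice* when the chosen option's value at decision time
is at least the unchosen option's (ties count as ideal, which makes the first
trial of every block ideal under the symmetric Q = (0.5, 0.5) initialisation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

Q_INIT = (0.5, 0.5)
#: floor on per-trial choice probabilities inside the likelihood
LIKELIHOOD_EPS = 1e-12
BETA_MAX = 50.0
#: lower fit bound on alpha: at alpha = 0 the likelihood is flat in beta
#: (Q frozen at the initial tie, every p = 0.5), an unidentified boundary
#: that would also degenerate the tie-counts-as-ideal rule into flagging
#: every trial ideal. Excluding it keeps the fit identified.
ALPHA_MIN = 1e-3


class QState(NamedTuple):
    """Expected reward of the two options; both stay in [0, 1]."""

    q1: float
    q2: float


@dataclass(frozen=True)
class ModelParams:
    """Fitted learner parameters: learning rate and choice stochasticity."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= BETA_MAX:
            raise ValueError(f"beta must be in [0, {BETA_MAX}], got {self.beta}")


@dataclass
class FitResult:
    params: ModelParams
    nll: float
    n_trials_used: int
    converged: bool
    n_starts: int
    start_nlls: list[float] = field(default_factory=list)
    bias: float | None = None  # fitted decision bias, when requested


def double_update(state: QState, chosen: int, reward: int, alpha: float) -> QState:
    """Apply one double-update step.

    Parameters
    ----------
    state : QState
    chosen : int
        1 or 2, the option that was chosen.
    reward : int
        0 or 1, the outcome received for the chosen option.
    alpha : float
        Learning rate in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward}")
    if chosen not in (1, 2):
        raise ValueError(f"chosen must be 1 or 2, got {chosen}")
    q1, q2 = state
    r = float(reward)
    if chosen == 1:
        q1 = q1 + alpha * (r - q1)
        q2 = q2 + alpha * ((1.0 - r) - q2)
    else:
        q2 = q2 + alpha * (r - q2)
        q1 = q1 + alpha * ((1.0 - r) - q1)
    return QState(q1, q2)


def choice_probability(state: QState, beta: float, bias: float = 0.0) -> float:
    """Softmax probability of choosing option 1.

    p1 = 1 / (1 + exp(-(beta * (q1 - q2) + bias))), overflow-safe.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return float(expit(beta * (state.q1 - state.q2) + bias))


def _blocks_from_trials(trials: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a trial table into per-block (choice, reward) integer arrays.

    Missing trials are dropped here; the Q trajectory is unaffected because
    missing trials trigger no update.
    """
    required = {"block", "choice", "reward", "missing"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    blocks = []
    for _, blk in trials.groupby("block", sort=True):
        obs = blk.loc[~blk["missing"].astype(bool)]
        blocks.append(
            (obs["choice"].to_numpy(dtype=np.int64), obs["reward"].to_numpy(dtype=np.int64))
        )
    return blocks


def _nll_blocks(
    alpha: float,
    beta: float,
    blocks: Sequence[tuple[np.ndarray, np.ndarray]],
    bias: float = 0.0,
) -> float:
    total = 0.0
    for choices, rewards in blocks:
        q1, q2 = Q_INIT
        for c, r in zip(choices, rewards):
            x = beta * (q1 - q2) + bias
            # overflow-safe logistic
            p1 = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
            p = p1 if c == 1 else 1.0 - p1
            if p < LIKELIHOOD_EPS:
                p = LIKELIHOOD_EPS
            total -= math.log(p)
            rf = float(r)
            if c == 1:
                q1 += alpha * (rf - q1)
                q2 += alpha * ((1.0 - rf) - q2)
            else:
                q2 += alpha * (rf - q2)
                q1 += alpha * ((1.0 - rf) - q1)
    return total


def negative_log_likelihood(params: ModelParams, trials: pd.DataFrame) -> float:
    """Negative log-likelihood (nats) of the observed choices under ``params``.

    Q resets to (0.5, 0.5) at every block start; missing trials contribute
    nothing and trigger no update. Raises on an empty (all-missing) trial set.
    """
    blocks = _blocks_from_trials(trials)
    n_obs = sum(len(c) for c, _ in blocks)
    if n_obs == 0:
        raise ValueError("no non-missing trials: likelihood undefined")
    return _nll_blocks(params.alpha, params.beta, blocks)


def fit_mle(
    trials: pd.DataFrame,
    n_starts: int = 10,
    seed: int | None = 0,
    bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (ALPHA_MIN, 1.0),
        (0.0, BETA_MAX),
    ),
    fit_bias: bool = False,
    bias_bounds: tuple[float, float] = (-10.0, 10.0),
) -> FitResult:
    """Maximum-likelihood fit of (alpha, beta) by bounded multi-start L-BFGS-B.

    Start points are a Latin-hypercube design over the bounds (seeded, so the
    fit is deterministic). Fewer than 20 usable trials triggers a warning.
    ``fit_bias=True`` additionally estimates an additive decision bias toward
    option 1 (off by default: the standard scoring model has two parameters).
    """
    blocks = _blocks_from_trials(trials)
    n_obs = sum(len(c) for c, _ in blocks)
    if n_obs == 0:
        raise ValueError("no non-missing trials to fit")
    if n_obs < 20:
        warnings.warn(f"only {n_obs} non-missing trials; estimates will be noisy", stacklevel=2)

    dims = [bounds[0], bounds[1]] + ([bias_bounds] if fit_bias else [])
    sampler = qmc.LatinHypercube(d=len(dims), seed=seed)
    unit = sampler.random(n=n_starts)
    lo = np.array([d[0] for d in dims])
    hi = np.array([d[1] for d in dims])
    starts = qmc.scale(unit, lo, hi)

    def objective(x: np.ndarray) -> float:
        return _nll_blocks(x[0], x[1], blocks, x[2] if fit_bias else 0.0)

    best = None
    start_nlls: list[float] = []
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=dims, options={"ftol": 1e-8}
        )
        start_nlls.append(float(res.fun))
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    alpha, beta = float(np.clip(best.x[0], 0, 1)), float(np.clip(best.x[1], 0, BETA_MAX))
    return FitResult(
        params=ModelParams(alpha=alpha, beta=beta),
        nll=float(best.fun),
        n_trials_used=n_obs,
        converged=any_ok,
        n_starts=n_starts,
        start_nlls=start_nlls,
        bias=float(best.x[2]) if fit_bias else None,
    )


def classify_ideal_choices(
    params: ModelParams, trials: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Flag each trial as ideal or not and return the ideal-choice proportion.

    A trial is ideal when the chosen option's model value at decision time is
    >= the unchosen option's (ties ideal; first trial of each block is a tie
    under the symmetric initialisation, hence always ideal). Adds columns:

    ``ideal``        pandas nullable boolean; NA on missing trials
    ``ideal_option`` 1 or 2 when one option strictly dominates, 0 on ties

    The proportion excludes missing trials. The Q trajectory is traced with
    ``params`` over non-missing trials, resetting at each block start.
    """
    out = trials.copy()
    blocks = out["block"].to_numpy()
    choices = out["choice"].to_numpy(dtype=np.int64)
    rewards = out["reward"].to_numpy(dtype=np.int64)
    missing = out["missing"].to_numpy(dtype=bool)
    alpha = params.alpha
    ideal = np.full(len(out), -1, dtype=np.int64)  # -1 = missing/NA
    ideal_option = np.zeros(len(out), dtype=np.int64)
    for b in np.unique(blocks):
        q1, q2 = Q_INIT
        for i in np.flatnonzero(blocks == b):
            if missing[i]:
                continue
            c = choices[i]
            if q1 > q2:
                ideal_option[i] = 1
            elif q2 > q1:
                ideal_option[i] = 2
            q_chosen, q_unchosen = (q1, q2) if c == 1 else (q2, q1)
            ideal[i] = int(q_chosen >= q_unchosen)
            r = float(rewards[i])
            if c == 1:
                q1 += alpha * (r - q1)
                q2 += alpha * ((1.0 - r) - q2)
            else:
                q2 += alpha * (r - q2)
                q1 += alpha * ((1.0 - r) - q1)
    out["ideal"] = pd.array([bool(v) if v >= 0 else pd.NA for v in ideal], dtype="boolean")
    out["ideal_option"] = ideal_option
    observed = out.loc[~out["missing"].astype(bool), "ideal"]
    proportion = float(observed.astype(bool).mean()) if len(observed) else float("nan")
    return out, proportion


def fit_cohort(
    trials: pd.DataFrame, n_starts: int = 10, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the model per participant x visit x condition and flag ideal choices.

    Returns ``(fits, flagged_trials)``: one fit row per cell (alpha, beta,
    nll, n_trials_used, prop_ideal) and the trial table with ideal columns.
    """
    fits = []
    flagged_parts = []
    keys = ["participant_id", "visit", "condition"]
    for i, (key, cell) in enumerate(trials.groupby(keys, sort=True)):
        res = fit_mle(cell, n_starts=n_starts, seed=seed + i)
        flagged, prop = classify_ideal_choices(res.params, cell)
        flagged_parts.append(flagged)
        fits.append(
            dict(
                zip(keys, key),
                alpha=res.params.alpha,
                beta=res.params.beta,
                nll=res.nll,
                n_trials_used=res.n_trials_used,
                converged=res.converged,
                prop_ideal=prop,
            )
        )
    return pd.DataFrame(fits), pd.concat(flagged_parts).sort_index()
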