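from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emolearn import cohort, rl, task


def true_param_proportions(
    labels: pd.DataFrame,
    trials: pd.DataFrame,
    param_map: dict[tuple[str, str], task.AgentParams],
) -> pd.DataFrame:
    """Ideal-choice proportions classified with the generating parameters.

    Bypasses maximum-likelihood fitting (the slow stage) for Monte-Carlo
    checks of the simulator's group-level structure; the classification rule
    itself is the production one.
    """
    lab = labels.set_index("participant_id")["label"]
    rows = []
    for (pid, visit, cond), cell in trials.groupby(["participant_id", "visit", "condition"]):
        p = param_map[(lab[pid], visit)]
        params = rl.ModelParams(alpha=min(p.alpha, 1.0), beta=min(p.beta, rl.BETA_MAX))
        _, prop = rl.classify_ideal_choices(params, cell)
        rows.append(
            {
                "participant_id": pid,
                "group": lab[pid],
                "visit": visit,
                "condition": cond,
                "prop_ideal": prop,
            }
        )
    return pd.DataFrame(rows)


def true_param_flagged(
    labels: pd.DataFrame,
    trials: pd.DataFrame,
    param_map: dict[tuple[str, str], task.AgentParams],
) -> pd.DataFrame:
    """Trial table with ideal flags traced at the generating parameters."""
    lab = labels.set_index("participant_id")["label"]
    parts = []
    for (pid, visit, _), cell in trials.groupby(["participant_id", "visit", "condition"]):
        p = param_map[(lab[pid], visit)]
        params = rl.ModelParams(alpha=min(p.alpha, 1.0), beta=min(p.beta, rl.BETA_MAX))
        flagged, _ = rl.classify_ideal_choices(params, cell)
        parts.append(flagged)
    return pd.concat(parts).sort_index()


@pytest.fixture(scope="session")
def small_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Default-size synthetic cohort (15 resistant / 35 responsive)."""
    return cohort.generate_cohort(seed=123)


@pytest.fixture(scope="session")
def simulated_trials(small_cohort) -> pd.DataFrame:
    _, labels = small_cohort
    analysed = labels.loc[labels["label"] != "unclassified"]
    return task.simulate_visits(analysed, seed=456)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
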