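"""Behavioural statistics: chance-level tests on ideal-choice proportions,
the 2 x 2 x 2 mixed ANOVA, and the emotional-bias score with its ANOVA.

The emotional-bias score quantifies the prepotent pull toward the happy
face: P(choose happy | the angry face is model-ideal) minus
P(choose angry | the happy face is model-ideal). Positive scores mean the
participant keeps choosing the happy face even when the learned values say
the angry face pays better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import mixed_anova
from .task import EMOTIONAL, HAPPY_OPTION

BONFERRONI_ALPHA = 0.05 / 8  # eight one-sample tests: 2 groups x 2 visits x 2 conditions
CHANCE_LEVEL = 0.5
ANGRY_OPTION = 2


@dataclass(frozen=True)
class EmotionalBiasScore:
    participant_id: str
    visit: str
    score: float  # NaN when undefined
    n_angry_ideal: int
    n_happy_ideal: int


def cell_summaries(props: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n of ideal-choice proportions per group x visit x condition."""
    g = props.groupby(["group", "visit", "condition"])["prop_ideal"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    return out


def chance_tests(
    props: pd.DataFrame,
    chance: float = CHANCE_LEVEL,
    adjusted_alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """One-sample t-tests of each cell's proportions against chance (0.5).

    One test per group x visit x condition cell (eight with the study's two
    groups); the significance flag uses the Bonferroni-adjusted threshold
    0.00625 = 0.05 / 8. Cells with n < 2 are reported but skipped.
    """
    rows = []
    for (group, visit, condition), cell in props.groupby(["group", "visit", "condition"]):
        x = cell["prop_ideal"].dropna().to_numpy()
        row = {
            "group": group,
            "visit": visit,
            "condition": condition,
            "n": len(x),
            "mean": float(np.mean(x)) if len(x) else np.nan,
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
        }
        if len(x) < 2:
            row.update(t=np.nan, df=np.nan, p=np.nan, above_chance=False, skipped=True)
        elif np.ptp(x) == 0:  # degenerate zero-variance cell
            t = 0.0 if x[0] == chance else np.sign(x[0] - chance) * np.inf
            p = 1.0 if t == 0 else 0.0
            row.update(
                t=t, df=len(x) - 1, p=p,
                above_chance=bool(p < adjusted_alpha and x[0] > chance), skipped=False,
            )
        else:
            t, p = stats.ttest_1samp(x, chance)
            row.update(
                t=float(t),
                df=len(x) - 1,
                p=float(p),
                above_chance=bool(p < adjusted_alpha and np.mean(x) > chance),
                skipped=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def mixed_anova_2x2x2(props: pd.DataFrame) -> pd.DataFrame:
    """Group (between) x visit x condition (within) mixed ANOVA on proportions.

    ``props`` is long format with columns participant_id, group, visit,
    condition, prop_ideal. Returns F, df, p and partial eta squared per effect.
    """
    return mixed_anova(
        props,
        dv="prop_ideal",
        subject="participant_id",
        between="group",
        within=["visit", "condition"],
    )


def emotional_bias(flagged_trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x visit emotional-bias scores from flagged trials.

    Uses the emotional-condition trials' ``ideal_option`` column (which face
    the fitted model deems higher-valued at decision time; 0 on value ties).
    Tie trials and missing trials never enter the conditioning sets. The
    score is NaN (flagged undefined) when either conditioning set is empty.
    """
    emo = flagged_trials.loc[
        (flagged_trials["condition"] == EMOTIONAL) & (~flagged_trials["missing"].astype(bool))
    ]
    rows = []
    for (pid, visit), df in emo.groupby(["participant_id", "visit"]):
        angry_ideal = df.loc[df["ideal_option"] == ANGRY_OPTION]
        happy_ideal = df.loc[df["ideal_option"] == HAPPY_OPTION]
        n_a, n_h = len(angry_ideal), len(happy_ideal)
        if n_a == 0 or n_h == 0:
            score = np.nan
        else:
            p_happy_given_angry = (angry_ideal["choice"] == HAPPY_OPTION).mean()
            p_angry_given_happy = (happy_ideal["choice"] == ANGRY_OPTION).mean()
            score = float(p_happy_given_angry - p_angry_given_happy)
        rows.append(
            {
                "participant_id": pid,
                "visit": visit,
                "score": score,
                "n_angry_ideal": n_a,
                "n_happy_ideal": n_h,
            }
        )
    return pd.DataFrame(rows)


def bias_anova(scores: pd.DataFrame) -> pd.DataFrame:
    """Group (between) x visit (within) mixed ANOVA on emotional-bias scores.

    Participants with an undefined score at either visit are dropped (logged
    in the table attrs).
    """
    data = scores.dropna(subset=["score"])
    return mixed_anova(
        data, dv="score", subject="participant_id", between="group", within=["visit"]
    )


def overall_bias_mean(scores: pd.DataFrame) -> tuple[float, float]:
    """Grand mean and SE of the per-participant bias scores pooled over visits."""
    per_participant = scores.dropna(subset=["score"]).groupby("participant_id")["score"].mean()
    return float(per_participant.mean()), float(per_participant.sem())
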