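"""Participant records, rule-based treatment-resistance labels, synthetic cohorts.

Treatment-resistance is assigned at the one-year follow-up (visit C) from
consensus-style operational criteria: a persisting positive-symptom threshold
on the PANSS positive subscale, at least two adequate antipsychotic trials,
adequate adherence, and low social-occupational functioning (SOFA < 60).
Responders are adherent participants below the symptom threshold at both the
six-month (B) and one-year (C) visits; everyone else is unclassified and is
excluded from downstream analyses with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_PANSS_POSITIVE_ITEMS = 7
SOFA_CUTOFF = 60
MIN_ADEQUATE_TRIALS = 2


class GroupLabel(str, Enum):
    RESISTANT = "resistant"
    RESPONSIVE = "responsive"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ParticipantRecord:
    """Clinical fields for one participant at one visit."""

    participant_id: str
    visit: str  # "A", "B" or "C"
    panss_positive_items: tuple[int, ...]
    panss_positive_total: int = 0
    panss_negative_total: int = 0
    panss_general_total: int = 0
    sofa: int = 100
    adequate_med_trials: int = 0
    adherent: bool = False
    cpz_equivalent: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        _validate_items(self.panss_positive_items)
        if not 0 <= self.sofa <= 100:
            raise ValueError(f"sofa must be in [0, 100], got {self.sofa}")
        if self.adequate_med_trials < 0:
            raise ValueError("adequate_med_trials must be >= 0")
        if self.visit not in ("A", "B", "C"):
            raise ValueError(f"visit must be A, B or C, got {self.visit}")


def _validate_items(items: Sequence[int]) -> None:
    if len(items) != N_PANSS_POSITIVE_ITEMS:
        raise ValueError(
            f"expected {N_PANSS_POSITIVE_ITEMS} PANSS positive item scores, got {len(items)}"
        )
    for s in items:
        if not 1 <= int(s) <= 7:
            raise ValueError(f"PANSS item scores must be in [1, 7], got {s}")


def meets_symptom_threshold(items: Sequence[int]) -> bool:
    """Positive-symptom threshold: one item >= 5, or two or more items >= 4."""
    _validate_items(items)
    arr = np.asarray(items, dtype=int)
    return bool(arr.max() >= 5 or (arr >= 4).sum() >= 2)


def classify_treatment_response(
    records: Mapping[str, ParticipantRecord],
) -> tuple[GroupLabel, str]:
    """Assign resistant / responsive / unclassified from visit A-C records.

    Returns ``(label, reason)``. Resistant: symptom threshold met at C, >= 2
    adequate medication trials, adherent, SOFA < 60. Responsive: adherent and
    below threshold at both B and C (six-month symptom stability). Anything
    else is unclassified with the first failing reason recorded.
    """
    if "C" not in records:
        return GroupLabel.UNCLASSIFIED, "missing visit C record"
    rec_c = records["C"]
    met_c = meets_symptom_threshold(rec_c.panss_positive_items)
    if met_c:
        if rec_c.adequate_med_trials < MIN_ADEQUATE_TRIALS:
            return GroupLabel.UNCLASSIFIED, "symptom threshold met but < 2 adequate trials"
        if not rec_c.adherent:
            return GroupLabel.UNCLASSIFIED, "symptom threshold met but not adherent"
        if rec_c.sofa >= SOFA_CUTOFF:
            return GroupLabel.UNCLASSIFIED, "symptom threshold met but SOFA >= 60"
        return GroupLabel.RESISTANT, "threshold at C, >=2 trials, adherent, SOFA < 60"
    if "B" not in records:
        return GroupLabel.UNCLASSIFIED, "missing visit B record"
    if not rec_c.adherent:
        return GroupLabel.UNCLASSIFIED, "below threshold but not adherent"
    if meets_symptom_threshold(records["B"].panss_positive_items):
        return GroupLabel.UNCLASSIFIED, "threshold met at B (no 6-month stability)"
    return GroupLabel.RESPONSIVE, "below threshold at B and C, adherent"


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort sizes and clinical sampling ranges (study defaults)."""

    n_resistant: int = 15
    n_responsive: int = 35
    n_males: tuple[int, int] = (11, 25)  # (resistant, responsive)

    def __post_init__(self) -> None:
        if self.n_resistant < 0 or self.n_responsive < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_males[0] > self.n_resistant or self.n_males[1] > self.n_responsive:
            raise ValueError("male counts cannot exceed group sizes")


def _sample_items(rng: np.random.Generator, above: bool) -> tuple[int, ...]:
    """Draw 7 PANSS positive item scores either meeting the threshold or not."""
    if above:
        items = rng.integers(1, 5, size=N_PANSS_POSITIVE_ITEMS)
        k = int(rng.integers(0, 2))
        if k == 0:  # one item at >= 5
            items[rng.integers(0, N_PANSS_POSITIVE_ITEMS)] = rng.integers(5, 8)
        else:  # two items at >= 4
            idx = rng.choice(N_PANSS_POSITIVE_ITEMS, size=2, replace=False)
            items[idx] = rng.integers(4, 8, size=2)
    else:
        items = rng.integers(1, 4, size=N_PANSS_POSITIVE_ITEMS)  # all < 4: neither clause
    return tuple(int(x) for x in items)


def _make_participant(
    pid: str, label: GroupLabel, rng: np.random.Generator, sex: str
) -> list[ParticipantRecord]:
    resistant = label is GroupLabel.RESISTANT
    records = []
    for visit in ("A", "B", "C"):
        above = resistant and visit in ("B", "C") or (resistant and visit == "A" and rng.random() < 0.8)
        items = _sample_items(rng, above=above if resistant else False)
        pos_total = int(sum(items))
        records.append(
            ParticipantRecord(
                participant_id=pid,
                visit=visit,
                panss_positive_items=items,
                panss_positive_total=pos_total,
                panss_negative_total=int(np.clip(rng.normal(17 if resistant else 12, 4), 7, 42)),
                panss_general_total=int(np.clip(rng.normal(35 if resistant else 20, 6), 16, 96)),
                sofa=int(rng.integers(35, SOFA_CUTOFF) if resistant else rng.integers(55, 95)),
                adequate_med_trials=int(rng.integers(2, 5) if resistant else rng.integers(1, 4)),
                adherent=True,
                cpz_equivalent=float(np.round(np.clip(rng.normal(240, 110), 50, 800), 1)),
                sex=sex,
            )
        )
    return records


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort whose records satisfy their intended label.

    Returns ``(participants, labels)``: a long table with one row per
    participant x visit, and a label table (participant_id, label, reason)
    as produced by re-running :func:`classify_treatment_response` on the
    generated records. Deterministic for a fixed seed.
    """
    config = CohortConfig() if config is None else config
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[ParticipantRecord] = []
    plan = [(GroupLabel.RESISTANT, config.n_resistant, config.n_males[0]), (
        GroupLabel.RESPONSIVE, config.n_responsive, config.n_males[1])]
    i = 0
    for label, n, n_male in plan:
        for j in range(n):
            i += 1
            pid = f"P{i:03d}"
            sex = "M" if j < n_male else "F"
            rows.extend(_make_participant(pid, label, rng, sex))
    participants = records_to_table(rows)
    labels = label_table(rows)
    return participants, labels


def records_to_table(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {
            "participant_id": r.participant_id,
            "visit": r.visit,
            **{f"panss_p{k + 1}": v for k, v in enumerate(r.panss_positive_items)},
            "panss_positive_total": r.panss_positive_total,
            "panss_negative_total": r.panss_negative_total,
            "panss_general_total": r.panss_general_total,
            "sofa": r.sofa,
            "adequate_med_trials": r.adequate_med_trials,
            "adherent": r.adherent,
            "cpz_equivalent": r.cpz_equivalent,
            "sex": r.sex,
        }
        rows.append(d)
    return pd.DataFrame(rows)


def table_to_records(table: pd.DataFrame) -> dict[str, dict[str, ParticipantRecord]]:
    """Parse a participant table back into per-participant, per-visit records."""
    item_cols = [f"panss_p{k + 1}" for k in range(N_PANSS_POSITIVE_ITEMS)]
    out: dict[str, dict[str, ParticipantRecord]] = {}
    for _, row in table.iterrows():
        rec = ParticipantRecord(
            participant_id=row["participant_id"],
            visit=row["visit"],
            panss_positive_items=tuple(int(row[c]) for c in item_cols),
            panss_positive_total=int(row["panss_positive_total"]),
            panss_negative_total=int(row["panss_negative_total"]),
            panss_general_total=int(row["panss_general_total"]),
            sofa=int(row["sofa"]),
            adequate_med_trials=int(row["adequate_med_trials"]),
            adherent=bool(row["adherent"]),
            cpz_equivalent=None if pd.isna(row.get("cpz_equivalent")) else float(row["cpz_equivalent"]),
            sex=row.get("sex"),
        )
        out.setdefault(rec.participant_id, {})[rec.visit] = rec
    return out


def label_table(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Classify every participant in a record collection; tidy label table."""
    by_pid: dict[str, dict[str, ParticipantRecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, {})[r.visit] = r
    rows = []
    for pid in sorted(by_pid):
        lab, reason = classify_treatment_response(by_pid[pid])
        rows.append({"participant_id": pid, "label": lab.value, "reason": reason})
    return pd.DataFrame(rows)


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify a participant x visit table read from CSV."""
    recs = table_to_records(table)
    rows = []
    for pid in sorted(recs):
        lab, reason = classify_treatment_response(recs[pid])
        rows.append({"participant_id": pid, "label": lab.value, "reason": reason})
    return pd.DataFrame(rows)
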