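"""Interview-quality dependent variables and the integrated quality factor.

Each interview is coded into six DVs — number of recommended questions,
number of not-recommended questions, proportion of recommended questions (%),
and counts of relevant, neutral, and incorrect details — plus two conclusion
flags.  The integrated factor summarizes quality as the mean of the six
per-DV z-scores, with the signs of the not-recommended-question and
incorrect-detail z-scores reversed so that larger is always better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import ExperimentDataset, InterviewRecord
from .engine import DETAIL_KINDS, ResponseKind
from .questions import QuestionType
from .scenarios import AvatarScenario

#: The six dependent variables, in reporting order.
DV_COLUMNS = [
    "n_recommended",
    "n_not_recommended",
    "prop_recommended",
    "n_relevant",
    "n_neutral",
    "n_incorrect",
]

#: DVs whose z-scores enter the integrated factor with reversed sign.
REVERSED_DVS = frozenset({"n_not_recommended", "n_incorrect"})


class ComputationError(ValueError):
    """A statistic cannot be computed from the data given (e.g. zero variance)."""


@dataclass
class MetricsRow:
    participant_id: str
    group: str
    interview_index: int
    avatar_id: str
    n_recommended: int
    n_not_recommended: int
    prop_recommended: float  # percent; NaN for a zero-question interview
    n_relevant: int
    n_neutral: int
    n_incorrect: int
    conclusion_correct: bool
    presence_correct: bool


def conclusion_correct(rec: InterviewRecord, s: AvatarScenario) -> bool:
    """Whether the interviewer's conclusion is fully correct.

    Requires the presence judgment to match ground truth.  For an abused
    scenario every concluded slot (who, where, what) must additionally match
    the scenario outcome; for a non-abused scenario no incorrect abuse claim
    may have been assented to.
    """
    judged_present = rec.post_judgment.presence == "present"
    if judged_present != s.abused:
        return False
    if s.abused:
        concluded = tuple(x.strip().casefold() for x in rec.concluded_slots.as_tuple())
        truth = tuple(x.strip().casefold() for x in s.outcome.as_tuple())
        return concluded == truth
    return not any(t.created_incorrect for t in rec.turns)


def code_interview(rec: InterviewRecord, s: AvatarScenario) -> MetricsRow:
    """Code one transcript into the six DVs plus conclusion flags."""
    n_rec = n_notrec = n_relevant = n_neutral = n_incorrect = 0
    for turn in rec.turns:
        qtype = turn.question.qtype
        if not isinstance(qtype, QuestionType):
            raise ValueError(f"transcript contains unknown question type {qtype!r}")
        if qtype.is_recommended:
            n_rec += 1
        else:
            n_notrec += 1
        if turn.response_kind is ResponseKind.RELEVANT_DETAIL:
            n_relevant += 1
        elif turn.response_kind is ResponseKind.NEUTRAL_DETAIL:
            n_neutral += 1
        n_incorrect += len(turn.created_incorrect)
    total = n_rec + n_notrec
    prop = 100.0 * n_rec / total if total > 0 else math.nan
    return MetricsRow(
        participant_id=rec.participant_id,
        group=rec.group,
        interview_index=rec.interview_index,
        avatar_id=rec.avatar_id,
        n_recommended=n_rec,
        n_not_recommended=n_notrec,
        prop_recommended=prop,
        n_relevant=n_relevant,
        n_neutral=n_neutral,
        n_incorrect=n_incorrect,
        conclusion_correct=conclusion_correct(rec, s),
        presence_correct=(rec.post_judgment.presence == "present") == s.abused,
    )


def experiment_table(dataset: ExperimentDataset) -> pd.DataFrame:
    """One MetricsRow per interview, as a DataFrame (the experiment table)."""
    rows = [code_interview(rec, dataset.scenario_for(rec)) for rec in dataset.records]
    return pd.DataFrame([vars(r) for r in rows])


def integrated_factor(
    table: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Append the integrated quality factor column to a metrics table.

    z-scores are computed per DV over the standardization population —
    ``reference`` when given, else ``table`` itself, pooled over all
    participant x interview rows — and the factor is the mean of the six
    signed z-scores (reversed for not-recommended questions and incorrect
    details).  Sample standard deviations (ddof=1) are used.
    """
    ref = table if reference is None else reference
    if len(ref) < 2:
        raise ComputationError("integrated factor needs >= 2 rows to standardize")
    out = table.copy()
    zsum = 0.0
    for dv in DV_COLUMNS:
        mean = ref[dv].mean()
        sd = ref[dv].std(ddof=1)
        if not sd > 0:
            raise ComputationError(f"dependent variable {dv!r} has zero variance")
        z = (out[dv] - mean) / sd
        zsum = zsum + (-z if dv in REVERSED_DVS else z)
    out["factor"] = zsum / len(DV_COLUMNS)
    return out
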