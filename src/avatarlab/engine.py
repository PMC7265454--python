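"""Answer-selection engine: map a coded question to an avatar response.

The avatar releases its 9+9 memory details only through recommended questions,
one detail per successful Bernoulli draw whose success probability depends on
the avatar's age (12.5% at age 4, 25% at age 6).  Details come out in a fixed
order within each category; the category of a successful draw is chosen by a
fair coin (falling back to the other category when one is exhausted).  A
recommended question whose keyword matches the side-detail bank short-circuits
the draw and returns the next unconsumed side answer verbatim.

Not-recommended questions never yield memory or side details.  When such a
question presupposes content that contradicts the avatar's memory, the avatar
assents with an age-dependent probability (30% at age 4), thereby creating an
*incorrect detail* — an assertion inconsistent with its predefined answer set.
Assertions consistent with memory are confirmed deterministically.  All other
not-recommended types draw a type-tagged generic/no-new-info response.

Random stream contract: for a recommended question, a side-bank hit consumes
no draws; otherwise one uniform is consumed for the detail Bernoulli, then one
for the category coin on success, or one for the generic/no-new-info choice on
failure.  A contradicting assertion consumes exactly one uniform; a consistent
assertion consumes none; other not-recommended types consume one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .questions import QuestionType
from .scenarios import AvatarScenario, Detail, N_DETAILS_PER_CATEGORY


class InterviewOverError(RuntimeError):
    """Raised when a question arrives after the question budget is spent."""


class ResponseKind(str, Enum):
    RELEVANT_DETAIL = "relevant_detail"
    NEUTRAL_DETAIL = "neutral_detail"
    SIDE_DETAIL = "side_detail"
    ASSENT = "assent"
    DENIAL = "denial"
    NO_NEW_INFO = "no_new_info"
    GENERIC = "generic"


DETAIL_KINDS = frozenset({ResponseKind.RELEVANT_DETAIL, ResponseKind.NEUTRAL_DETAIL})


@dataclass(frozen=True)
class Assertion:
    """A proposition a leading question presupposes.

    ``consistent_with_memory`` is the coded truth value against the scenario's
    predefined answer set; when None it is resolved by text match against the
    memory details and outcome slots.
    """

    text: str
    consistent_with_memory: bool | None = None


@dataclass
class CodedQuestion:
    """An operator-coded interviewer question — the engine's sole input."""

    qtype: QuestionType
    text: str | None = None
    keyword: str | None = None
    asserted_content: Assertion | None = None

    def __post_init__(self) -> None:
        if self.asserted_content is not None and not self.qtype.carries_assertion:
            raise ValueError(
                f"asserted_content is only meaningful for option-posing/suggestive/"
                f"multiple-choice questions, not {self.qtype.value}"
            )


def _validated_age_probs(name: str, probs: dict[int, float]) -> dict[int, float]:
    if set(probs) != {4, 6}:
        raise ValueError(f"{name}: age keys must be exactly {{4, 6}}, got {sorted(probs)}")
    for age, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}[{age}]: probability {p} outside [0, 1]")
    return probs


@dataclass
class AlgorithmParams:
    """Stated response probabilities of the answer-selection algorithm.

    ``p_detail_by_age``: per-recommended-question probability of releasing a
    memory detail (0.125 at age 4, 0.25 at age 6).
    ``p_assent_suggestive_by_age``: probability of assenting to presupposed
    content that contradicts memory (0.30 at age 4; the age-6 default of 0.15
    is a package choice, not an empirically stated rate).
    ``p_generic_on_miss``: on a failed detail draw (or a non-assertion
    not-recommended question), probability of a generic filler response rather
    than an explicit no-new-info response.
    """

    p_detail_by_age: dict[int, float] = field(default_factory=lambda: {4: 0.125, 6: 0.25})
    p_assent_suggestive_by_age: dict[int, float] = field(default_factory=lambda: {4: 0.30, 6: 0.15})
    p_generic_on_miss: float = 0.7

    def __post_init__(self) -> None:
        _validated_age_probs("p_detail_by_age", self.p_detail_by_age)
        _validated_age_probs("p_assent_suggestive_by_age", self.p_assent_suggestive_by_age)
        if not 0.0 <= self.p_generic_on_miss <= 1.0:
            raise ValueError(f"p_generic_on_miss {self.p_generic_on_miss} outside [0, 1]")


@dataclass
class InterviewState:
    """Mutable per-interview elicitation state (cursors never decrease)."""

    scenario_id: str
    budget: int
    next_relevant_index: int = 1
    next_neutral_index: int = 1
    side_cursors: dict[str, int] = field(default_factory=dict)
    incorrect_details: list[Assertion] = field(default_factory=list)
    question_log: list[QuestionType] = field(default_factory=list)
    questions_asked: int = 0

    def details_exhausted(self) -> bool:
        return (
            self.next_relevant_index > N_DETAILS_PER_CATEGORY
            and self.next_neutral_index > N_DETAILS_PER_CATEGORY
        )


@dataclass
class Turn:
    """One question -> response exchange."""

    question: CodedQuestion
    response_kind: ResponseKind
    response_text: str
    elicited_detail: Detail | None = None
    created_incorrect: list[Assertion] = field(default_factory=list)


def new_interview_state(scenario: AvatarScenario, budget: int) -> InterviewState:
    if budget < 0:
        raise ValueError(f"budget must be >= 0, got {budget}")
    return InterviewState(
        scenario_id=scenario.id,
        budget=budget,
        side_cursors={key: 0 for key in scenario.side_bank.entries},
    )


def _assertion_consistent(assertion: Assertion, scenario: AvatarScenario) -> bool:
    if assertion.consistent_with_memory is not None:
        return assertion.consistent_with_memory
    text = assertion.text.strip().casefold()
    haystacks = [d.text.casefold() for d in scenario.all_details()]
    haystacks += [s.casefold() for s in scenario.outcome.as_tuple() if s]
    return any(text and text in h for h in haystacks)


def _take_detail(state: InterviewState, scenario: AvatarScenario, category: str) -> Detail | None:
    if category == "relevant" and state.next_relevant_index <= N_DETAILS_PER_CATEGORY:
        d = scenario.relevant_details[state.next_relevant_index - 1]
        state.next_relevant_index += 1
        return d
    if category == "neutral" and state.next_neutral_index <= N_DETAILS_PER_CATEGORY:
        d = scenario.neutral_details[state.next_neutral_index - 1]
        state.next_neutral_index += 1
        return d
    return None


def answer_question(
    state: InterviewState,
    scenario: AvatarScenario,
    params: AlgorithmParams,
    q: CodedQuestion,
    rng: np.random.Generator,
) -> tuple[Turn, InterviewState]:
    """Dispatch one coded question; mutates and returns ``state``."""
    if state.questions_asked >= state.budget:
        raise InterviewOverError(
            f"question budget of {state.budget} exhausted for scenario {state.scenario_id}"
        )
    if not isinstance(q.qtype, QuestionType):
        raise ValueError(f"unknown question type {q.qtype!r}")

    turn: Turn
    if q.qtype.is_recommended:
        side_key = scenario.side_bank.lookup_key(q.keyword)
        answers = scenario.side_bank.entries.get(side_key, []) if side_key else []
        cursor = state.side_cursors.get(side_key, 0) if side_key else 0
        if side_key is not None and cursor < len(answers):
            # side-bank hit: verbatim answer, no detail draw, no rng consumed
            state.side_cursors[side_key] = cursor + 1
            turn = Turn(q, ResponseKind.SIDE_DETAIL, answers[cursor])
        elif rng.random() < params.p_detail_by_age[scenario.age]:
            category = "relevant" if rng.random() < 0.5 else "neutral"
            detail = _take_detail(state, scenario, category)
            if detail is None:  # chosen category exhausted; try the other
                other = "neutral" if category == "relevant" else "relevant"
                detail = _take_detail(state, scenario, other)
            if detail is None:
                turn = Turn(q, ResponseKind.NO_NEW_INFO, "I already told you everything.")
            else:
                kind = (
                    ResponseKind.RELEVANT_DETAIL
                    if detail.category == "relevant"
                    else ResponseKind.NEUTRAL_DETAIL
                )
                turn = Turn(q, kind, detail.text, elicited_detail=detail)
        elif rng.random() < params.p_generic_on_miss:
            turn = Turn(q, ResponseKind.GENERIC, "Hmm... I don't know.")
        else:
            turn = Turn(q, ResponseKind.NO_NEW_INFO, "I can't think of anything else.")
    else:
        assertion = q.asserted_content
        if assertion is not None and not _assertion_consistent(assertion, scenario):
            if rng.random() < params.p_assent_suggestive_by_age[scenario.age]:
                turn = Turn(q, ResponseKind.ASSENT, "Yes.", created_incorrect=[assertion])
            else:
                turn = Turn(q, ResponseKind.DENIAL, "No.")
        elif assertion is not None:
            # consistent presupposition: the child confirms true content
            turn = Turn(q, ResponseKind.ASSENT, "Yes.")
        elif rng.random() < params.p_generic_on_miss:
            turn = Turn(q, ResponseKind.GENERIC, f"({q.qtype.value}) I'm not sure.")
        else:
            turn = Turn(q, ResponseKind.NO_NEW_INFO, "I don't want to say.")

    state.questions_asked += 1
    state.question_log.append(q.qtype)
    state.incorrect_details.extend(turn.created_incorrect)
    return turn, state


def detect_incorrect_details(turn: Turn, scenario: AvatarScenario) -> list[Assertion]:
    """Assertions in a turn that contradict the scenario's predefined answers.

    Pure function: inspects the turn only, mutates nothing.
    """
    assertion = turn.question.asserted_content
    if assertion is None or turn.response_kind is not ResponseKind.ASSENT:
        return []
    if _assertion_consistent(assertion, scenario):
        return []
    return [assertion]
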