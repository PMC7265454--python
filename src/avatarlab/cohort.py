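"""Synthetic trainee cohort and the full feedback-vs-control experiment.

Emulates the statistical structure of a 2 (feedback, control; between) x
6 (interview occasion; within) training study.  Each simulated trainee holds a
question-emitting policy: a propensity ``p_rec`` to ask a recommended question
(baseline drawn logit-normally around 0.441 with between-participant spread),
a subtype mix within each bucket, a per-interview question-count distribution
(truncated normal, mean 16.6, sd 8.5, minimum 1), and a keyword-attachment
rate.  After each of interviews 1-5, feedback-group trainees receive a 2+2
feedback set drawn from the transcript just produced; each feedback event adds
``learn_gain`` to ``p_rec`` (clamped to 1) and shifts the not-recommended
subtype mix away from the criticised types.  Control policies never change.

Everything is a pure function of the experiment configuration, including its
master seed, so any dataset can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .engine import (
    AlgorithmParams,
    Assertion,
    CodedQuestion,
    InterviewState,
    Turn,
    answer_question,
    new_interview_state,
)
from .questions import EXAMPLE_TEXTS, QuestionType
from .scenarios import AvatarScenario, Outcome, ScenarioBank, make_default_bank

N_INTERVIEWS = 6
CONFIDENCE_SCALE = (50, 60, 70, 80, 90, 100)

#: Monotone map from number of elicited conclusion-critical details (0..4) to
#: the reported confidence on the 6-point scale.
CONFIDENCE_BY_CRITICAL = {0: 50, 1: 60, 2: 70, 3: 80, 4: 100}

DEFAULT_REC_MIX: dict[QuestionType, float] = {
    QuestionType.INVITATION: 0.30,
    QuestionType.FACILITATOR: 0.35,
    QuestionType.DIRECTIVE: 0.35,
}

DEFAULT_NOTREC_MIX: dict[QuestionType, float] = {
    QuestionType.OPTION_POSING: 0.24,
    QuestionType.SPECIFIC_SUGGESTIVE: 0.20,
    QuestionType.UNSPECIFIC_SUGGESTIVE: 0.10,
    QuestionType.REPETITION: 0.08,
    QuestionType.TOO_LONG: 0.08,
    QuestionType.UNCLEAR: 0.07,
    QuestionType.MULTIPLE_CHOICE: 0.08,
    QuestionType.TIME: 0.06,
    QuestionType.FEELINGS: 0.06,
    QuestionType.FANTASY: 0.03,
}


@dataclass
class PolicyState:
    """A synthetic interviewer's question-generating parameters."""

    group: str  # "feedback" | "control"
    p_rec: float
    rec_mix: dict[QuestionType, float] = field(default_factory=lambda: dict(DEFAULT_REC_MIX))
    notrec_mix: dict[QuestionType, float] = field(default_factory=lambda: dict(DEFAULT_NOTREC_MIX))
    question_count_mean: float = 16.6
    question_count_sd: float = 8.5
    keyword_rate: float = 0.15
    learn_gain: float = 0.042
    assertion_true_rate: float = 0.2
    mix_step: float = 0.5

    def __post_init__(self) -> None:
        if self.group not in ("feedback", "control"):
            raise ValueError(f"group must be 'feedback' or 'control', got {self.group!r}")
        self.p_rec = float(np.clip(self.p_rec, 0.0, 1.0))


@dataclass(frozen=True)
class FeedbackItem:
    position: int  # 0-based transcript index
    qtype: QuestionType
    text: str


@dataclass
class FeedbackSet:
    recommended_items: list[FeedbackItem]
    not_recommended_items: list[FeedbackItem]
    covered_types: set[QuestionType]


@dataclass
class Judgment:
    presence: str  # "present" | "absent"
    confidence: int  # one of CONFIDENCE_SCALE

    def __post_init__(self) -> None:
        if self.presence not in ("present", "absent"):
            raise ValueError(f"presence must be 'present'/'absent', got {self.presence!r}")
        if self.confidence not in CONFIDENCE_SCALE:
            raise ValueError(f"confidence must be on {CONFIDENCE_SCALE}, got {self.confidence}")


@dataclass
class InterviewRecord:
    participant_id: str
    group: str
    interview_index: int  # 1..6
    avatar_id: str
    turns: list[Turn]
    pre_judgment: Judgment
    post_judgment: Judgment
    concluded_slots: Outcome
    p_rec_used: float


@dataclass
class ExperimentConfig:
    """Study conditions for one synthetic experiment."""

    n_feedback: int = 17
    n_control: int = 15
    n_interviews: int = N_INTERVIEWS
    bank: ScenarioBank | None = None  # default factorial bank when None
    params: AlgorithmParams = field(default_factory=AlgorithmParams)
    baseline_p_rec: float = 0.441
    baseline_logit_sd: float = 0.75
    learn_gain: float = 0.042
    keyword_rate: float = 0.15
    question_count_mean: float = 16.6
    question_count_sd: float = 8.5
    budget: int = 60
    assertion_true_rate: float = 0.2
    presence_noise: float = 0.05
    mix_step: float = 0.5
    seed: int = 0


@dataclass
class Participant:
    pid: str
    policy: PolicyState
    avatar_ids: list[str]


@dataclass
class ExperimentDataset:
    """All interview records plus the provenance needed for exact replay."""

    records: list[InterviewRecord]
    config: ExperimentConfig
    bank: ScenarioBank

    def scenario_for(self, record: InterviewRecord) -> AvatarScenario:
        return self.bank.get(record.avatar_id)


class ConfigurationError(ValueError):
    pass


def _resolve_bank(cfg: ExperimentConfig) -> ScenarioBank:
    return cfg.bank if cfg.bank is not None else make_default_bank(seed=0)


def build_cohort(cfg: ExperimentConfig, seed: int) -> list[Participant]:
    """Randomly allocate trainees to groups and assign 6 distinct avatars each."""
    bank = _resolve_bank(cfg)
    if len(bank) < cfg.n_interviews:
        raise ConfigurationError(
            f"scenario bank has {len(bank)} scenarios; need >= {cfg.n_interviews}"
        )
    rng = np.random.default_rng(seed)
    ids = bank.ids()
    participants: list[Participant] = []
    mu = logit(cfg.baseline_p_rec)
    for group, n in (("feedback", cfg.n_feedback), ("control", cfg.n_control)):
        for i in range(n):
            baseline = float(expit(rng.normal(mu, cfg.baseline_logit_sd)))
            policy = PolicyState(
                group=group,
                p_rec=baseline,
                question_count_mean=cfg.question_count_mean,
                question_count_sd=cfg.question_count_sd,
                keyword_rate=cfg.keyword_rate,
                learn_gain=cfg.learn_gain if group == "feedback" else 0.0,
                assertion_true_rate=cfg.assertion_true_rate,
                mix_step=cfg.mix_step,
            )
            avatar_ids = [ids[j] for j in rng.choice(len(ids), size=cfg.n_interviews, replace=False)]
            participants.append(
                Participant(pid=f"{group[0]}{i + 1:02d}", policy=policy, avatar_ids=avatar_ids)
            )
    return participants


def _sample_mix(mix: dict[QuestionType, float], rng: np.random.Generator) -> QuestionType:
    u = rng.random() * sum(mix.values())
    acc = 0.0
    qtype = next(iter(mix))
    for qtype, w in mix.items():
        acc += w
        if u <= acc:
            break
    return qtype


def sample_question(
    policy: PolicyState, state: InterviewState, rng: np.random.Generator
) -> CodedQuestion:
    """Emit one coded question from the trainee's current policy."""
    if rng.random() < policy.p_rec:
        qtype = _sample_mix(policy.rec_mix, rng)
        keyword = None
        if state.side_cursors and rng.random() < policy.keyword_rate:
            keys = sorted(state.side_cursors)
            keyword = keys[int(rng.integers(len(keys)))]
        text = EXAMPLE_TEXTS[qtype]
        if keyword is not None:
            text = f"Tell me more about {keyword}."
        return CodedQuestion(qtype=qtype, text=text, keyword=keyword)
    qtype = _sample_mix(policy.notrec_mix, rng)
    assertion = None
    if qtype.carries_assertion:
        consistent = bool(rng.random() < policy.assertion_true_rate)
        assertion = Assertion(
            text=f"presupposed content ({qtype.value})", consistent_with_memory=consistent
        )
    return CodedQuestion(qtype=qtype, text=EXAMPLE_TEXTS[qtype], asserted_content=assertion)


def _draw_question_count(policy: PolicyState, budget: int, rng: np.random.Generator) -> int:
    n = int(round(rng.normal(policy.question_count_mean, policy.question_count_sd)))
    return max(1, min(n, budget))


def run_interview(
    policy: PolicyState,
    scenario: AvatarScenario,
    params: AlgorithmParams,
    rng: np.random.Generator,
    *,
    participant_id: str = "p01",
    interview_index: int = 1,
    budget: int = 60,
    presence_noise: float = 0.05,
) -> InterviewRecord:
    """Simulate one full interview: question loop, judgments, conclusion."""
    state = new_interview_state(scenario, budget=budget)
    n_questions = _draw_question_count(policy, budget, rng)
    pre = Judgment(presence="present" if rng.random() < 0.5 else "absent", confidence=50)

    turns: list[Turn] = []
    for _ in range(n_questions):
        q = sample_question(policy, state, rng)
        turn, state = answer_question(state, scenario, params, q, rng)
        turns.append(turn)

    n_critical = sum(
        1 for t in turns if t.elicited_detail is not None and t.elicited_detail.conclusion_critical
    )
    n_incorrect = sum(len(t.created_incorrect) for t in turns)

    # Stand-in decision rule: abuse judged present when abuse-indicative
    # evidence surfaced — a conclusion-critical detail of a truly abused child,
    # or a falsely assented abuse assertion — with a small noise flip.
    evidence = (scenario.abused and n_critical >= 1) or (not scenario.abused and n_incorrect >= 1)
    presence = "present" if evidence else "absent"
    if rng.random() < presence_noise:
        presence = "absent" if presence == "present" else "present"

    concluded = (
        Outcome(*scenario.outcome.as_tuple()) if n_critical >= 4 else Outcome("", "", "")
    )
    post = Judgment(presence=presence, confidence=CONFIDENCE_BY_CRITICAL[min(n_critical, 4)])
    return InterviewRecord(
        participant_id=participant_id,
        group=policy.group,
        interview_index=interview_index,
        avatar_id=scenario.id,
        turns=turns,
        pre_judgment=pre,
        post_judgment=post,
        concluded_slots=concluded,
        p_rec_used=policy.p_rec,
    )


def select_feedback_items(
    rec: InterviewRecord, covered: set[QuestionType]
) -> FeedbackSet:
    """Pick up to 2 recommended + 2 not-recommended transcript questions.

    Question types not yet covered by earlier feedback occasions are chosen
    first; ties break by earliest transcript position; within a bucket the two
    items have distinct types whenever the transcript permits.
    """
    if not rec.turns:
        raise ValueError("cannot select feedback items from an empty transcript")

    def pick(bucket_recommended: bool) -> list[FeedbackItem]:
        candidates = [
            FeedbackItem(i, t.question.qtype, t.question.text or "")
            for i, t in enumerate(rec.turns)
            if t.question.qtype.is_recommended == bucket_recommended
        ]
        candidates.sort(key=lambda it: (it.qtype in covered, it.position))
        chosen: list[FeedbackItem] = []
        for item in candidates:  # distinct types first
            if len(chosen) == 2:
                break
            if all(item.qtype != c.qtype for c in chosen):
                chosen.append(item)
        for item in candidates:  # pad with repeats when types are scarce
            if len(chosen) == 2:
                break
            if item not in chosen:
                chosen.append(item)
        return sorted(chosen, key=lambda it: it.position)

    rec_items = pick(True)
    notrec_items = pick(False)
    new_covered = covered | {it.qtype for it in rec_items + notrec_items}
    return FeedbackSet(
        recommended_items=rec_items,
        not_recommended_items=notrec_items,
        covered_types=new_covered,
    )


def apply_feedback(policy: PolicyState, fs: FeedbackSet) -> PolicyState:
    """Return the post-feedback policy; ``p_rec`` never decreases."""
    if policy.group != "feedback":
        raise ValueError("apply_feedback called on a control-group policy")
    new_p = float(min(1.0, policy.p_rec + policy.learn_gain))
    new_mix = dict(policy.notrec_mix)
    criticised = {it.qtype for it in fs.not_recommended_items}
    if criticised:
        for qtype in criticised:
            new_mix[qtype] = new_mix[qtype] * (1.0 - policy.mix_step)
        total = sum(new_mix.values())
        new_mix = {t: w / total for t, w in new_mix.items()}
    return dataclasses.replace(policy, p_rec=new_p, notrec_mix=new_mix)


def run_experiment(cfg: ExperimentConfig) -> ExperimentDataset:
    """Run the full 2-group x 6-interview design from the master seed."""
    bank = _resolve_bank(cfg)
    cohort = build_cohort(cfg, cfg.seed)
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cohort))
    records: list[InterviewRecord] = []
    for participant, stream in zip(cohort, streams):
        rng = np.random.default_rng(stream)
        policy = participant.policy
        covered: set[QuestionType] = set()
        for j in range(1, cfg.n_interviews + 1):
            scenario = bank.get(participant.avatar_ids[j - 1])
            record = run_interview(
                policy,
                scenario,
                cfg.params,
                rng,
                participant_id=participant.pid,
                interview_index=j,
                budget=cfg.budget,
                presence_noise=cfg.presence_noise,
            )
            records.append(record)
            # feedback after interviews 1..5 only, feedback group only
            if policy.group == "feedback" and j < cfg.n_interviews:
                fs = select_feedback_items(record, covered)
                policy = apply_feedback(policy, fs)
                covered = fs.covered_types
    return ExperimentDataset(records=records, config=cfg, bank=bank)
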