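"""Question-type taxonomy for investigative interviews with children.

Thirteen codes partition every interviewer utterance.  Three *recommended*
types (invitation, facilitator, directive) are open and non-suggestive; they
elicit or extend free narrative and are the only channel through which an
avatar releases memory details.  The ten *not recommended* types are closed,
leading, or otherwise developmentally inappropriate; four of them
(option-posing, specific/unspecific suggestive, multiple-choice) can carry an
asserted proposition that the child may falsely assent to.
"""

from __future__ import annotations

from enum import Enum


class QuestionType(str, Enum):
    """One of the 13 codes an operator assigns to each interviewer question."""

    # recommended
    INVITATION = "invitation"
    FACILITATOR = "facilitator"
    DIRECTIVE = "directive"
    # not recommended
    OPTION_POSING = "option_posing"
    SPECIFIC_SUGGESTIVE = "specific_suggestive"
    UNSPECIFIC_SUGGESTIVE = "unspecific_suggestive"
    REPETITION = "repetition"
    TOO_LONG = "too_long"
    UNCLEAR = "unclear"
    MULTIPLE_CHOICE = "multiple_choice"
    TIME = "time"
    FEELINGS = "feelings"
    FANTASY = "fantasy"

    @property
    def is_recommended(self) -> bool:
        return self in RECOMMENDED_TYPES

    @property
    def carries_assertion(self) -> bool:
        """Whether this type may presuppose content absent from the child's account."""
        return self in ASSERTION_TYPES


RECOMMENDED_TYPES: frozenset[QuestionType] = frozenset(
    {QuestionType.INVITATION, QuestionType.FACILITATOR, QuestionType.DIRECTIVE}
)

NOT_RECOMMENDED_TYPES: frozenset[QuestionType] = frozenset(QuestionType) - RECOMMENDED_TYPES

# Types whose coded form may include a proposition the question presupposes.
ASSERTION_TYPES: frozenset[QuestionType] = frozenset(
    {
        QuestionType.OPTION_POSING,
        QuestionType.SPECIFIC_SUGGESTIVE,
        QuestionType.UNSPECIFIC_SUGGESTIVE,
        QuestionType.MULTIPLE_CHOICE,
    }
)

# Template texts used by the synthetic interviewer when emitting questions.
EXAMPLE_TEXTS: dict[QuestionType, str] = {
    QuestionType.INVITATION: "Tell me everything that happened from the beginning to the end",
    QuestionType.FACILITATOR: "What happened after that?",
    QuestionType.DIRECTIVE: "Where did you go with your mom?",
    QuestionType.OPTION_POSING: "Do you play with dad?",
    QuestionType.SPECIFIC_SUGGESTIVE: "Did your dad do something bad to you?",
    QuestionType.UNSPECIFIC_SUGGESTIVE: "I know that I have something to talk about, tell me!",
    QuestionType.REPETITION: "And what happened then? Tell me again.",
    QuestionType.TOO_LONG: "Where were you with your father, what were you doing after that?",
    QuestionType.UNCLEAR: "What is the relationship between mom and dad?",
    QuestionType.MULTIPLE_CHOICE: "Did you go practicing football with Kanta or Miura?",
    QuestionType.TIME: "When did your mom leave the park?",
    QuestionType.FEELINGS: "What do you think of your Grandpa?",
    QuestionType.FANTASY: "If you were your dad, what did you do?",
}
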