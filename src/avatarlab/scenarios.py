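"""Avatar scenarios: one simulated child per scenario, plus the default bank.

A scenario is the complete "memory" of a simulated child: nine *relevant*
details about the alleged incident, nine *neutral* details unrelated to it, a
keyword-indexed bank of verbatim *side details*, demographic attributes
(age 4 or 6, gender), a ground-truth abuse flag, and a structured outcome
(who / where / what actually happened).  The last four relevant details carry
the information required to reach the correct case conclusion.

The default bank holds 16 scenarios: two per cell of the
2 (age) x 2 (gender) x 2 (abuse) factorial.  Scenario files are YAML (JSON is
a subset); see ``docs/scenario_schema.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

AGES = (4, 6)
GENDERS = ("female", "male")
N_DETAILS_PER_CATEGORY = 9

#: 1-based positions of the relevant details that carry conclusion-critical
#: information (the last four of the nine).
CRITICAL_RELEVANT_INDICES = frozenset({6, 7, 8, 9})


class ScenarioFormatError(ValueError):
    """A scenario file could not be parsed against the documented schema."""


class ScenarioValidationError(ValueError):
    """A structurally parseable scenario violates a domain invariant."""


@dataclass(frozen=True)
class Detail:
    """One memory item, released at most once per interview, in index order."""

    index: int  # 1-based position in the fixed provision order
    category: str  # "relevant" | "neutral"
    text: str
    conclusion_critical: bool

    @staticmethod
    def make(index: int, category: str, text: str) -> "Detail":
        critical = category == "relevant" and index in CRITICAL_RELEVANT_INDICES
        return Detail(index=index, category=category, text=text, conclusion_critical=critical)


@dataclass
class SideDetailBank:
    """Keyword-indexed answer lists, consumed strictly in order.

    Keywords are matched case-insensitively after whitespace trimming.
    """

    entries: dict[str, list[str]] = field(default_factory=dict)

    def lookup_key(self, keyword: str | None) -> str | None:
        """Return the canonical stored key matching ``keyword``, or None."""
        if not keyword:
            return None
        want = keyword.strip().casefold()
        for key in self.entries:
            if key.strip().casefold() == want:
                return key
        return None


@dataclass
class Outcome:
    """Ground-truth conclusion slots describing what actually happened."""

    who: str = ""
    where: str = ""
    what: str = ""

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.who, self.where, self.what)


@dataclass
class AvatarScenario:
    id: str
    age: int
    gender: str
    abused: bool
    background: str
    relevant_details: list[Detail]
    neutral_details: list[Detail]
    side_bank: SideDetailBank
    outcome: Outcome

    def all_details(self) -> Iterator[Detail]:
        yield from self.relevant_details
        yield from self.neutral_details


@dataclass
class ScenarioBank:
    scenarios: list[AvatarScenario]

    def __len__(self) -> int:
        return len(self.scenarios)

    def get(self, scenario_id: str) -> AvatarScenario:
        for s in self.scenarios:
            if s.id == scenario_id:
                return s
        raise KeyError(f"no scenario with id {scenario_id!r}")

    def ids(self) -> list[str]:
        return [s.id for s in self.scenarios]


# ---------------------------------------------------------------------------
# validation

def validate_scenario(s: AvatarScenario) -> list[str]:
    """Return a description of every invariant violation (empty when valid).

    Total: never raises on structurally complete input.
    """
    violations: list[str] = []
    if s.age not in AGES:
        violations.append(f"age: expected one of {AGES}, got {s.age!r}")
    if s.gender not in GENDERS:
        violations.append(f"gender: expected one of {GENDERS}, got {s.gender!r}")
    for name, details, category in (
        ("relevant_details", s.relevant_details, "relevant"),
        ("neutral_details", s.neutral_details, "neutral"),
    ):
        if len(details) != N_DETAILS_PER_CATEGORY:
            violations.append(f"{name}: expected {N_DETAILS_PER_CATEGORY}, got {len(details)}")
        indices = [d.index for d in details]
        if sorted(indices) != list(range(1, len(details) + 1)):
            violations.append(f"{name}: indices must be 1..{len(details)} without gaps, got {indices}")
        for d in details:
            if d.category != category:
                violations.append(f"{name}[{d.index}]: category {d.category!r} != {category!r}")
            expected_crit = category == "relevant" and d.index in CRITICAL_RELEVANT_INDICES
            if d.conclusion_critical != expected_crit:
                violations.append(
                    f"{name}[{d.index}]: conclusion_critical must be {expected_crit} "
                    "(only the last four relevant details are critical)"
                )
    seen: set[str] = set()
    for key, answers in s.side_bank.entries.items():
        folded = key.strip().casefold()
        if folded in seen:
            violations.append(f"side_bank: duplicate keyword {key!r} (case-folded)")
        seen.add(folded)
        if not answers:
            violations.append(f"side_bank[{key!r}]: answer list must be non-empty")
    if s.abused and not all(s.outcome.as_tuple()):
        violations.append("outcome: abused scenario requires non-empty who/where/what slots")
    return violations


def validate_bank(bank: ScenarioBank) -> list[str]:
    violations: list[str] = []
    seen_ids: set[str] = set()
    for s in bank.scenarios:
        if s.id in seen_ids:
            violations.append(f"duplicate scenario id {s.id!r}")
        seen_ids.add(s.id)
        violations.extend(f"{s.id}: {v}" for v in validate_scenario(s))
    return violations


# ---------------------------------------------------------------------------
# default factorial bank

_SUSPECTS = ["his uncle", "her grandfather", "the group leader", "a neighbour",
             "the swimming coach", "her stepfather", "his babysitter", "the caretaker"]
_PLACES = ["in the storage room", "at the clubhouse", "in the garden shed",
           "at the swimming hall", "in the back of the van", "at the summer camp cabin"]
_ABUSE_ACTS = ["touched them under their clothes", "made them undress and took pictures",
               "touched them while bathing", "kissed them and told them to keep it secret"]
_INNOCENT_ACTS = ["helped them bandage a scraped knee", "showed them a litter of kittens",
                  "helped them change into dry clothes after the rain",
                  "gave them medicine for a stomach ache"]
_NEUTRAL_TOPICS = ["a red bicycle", "a school excursion", "a pet hamster", "a birthday party",
                   "a new video game", "football practice", "a drawing contest", "a picnic",
                   "a snowman", "a library book", "a paper plane", "a treehouse"]
_KEYWORDS = ["grandfather", "school", "friend", "pet", "holiday", "mom", "park"]


def _relevant_texts(rng: np.random.Generator, abused: bool,
                    who: str, where: str, what: str) -> list[str]:
    """Nine ordered relevant-detail texts; the last four embed the outcome."""
    lead_in = [
        "Something happened after the activity ended",
        "One grown-up often asked them to stay behind",
        "They were told not to tell anyone about it",
        "It happened more than once",
        "They felt strange about going back there",
    ]
    lead_in = [lead_in[i] for i in rng.permutation(len(lead_in))]
    tail = [
        f"It was {who} who was there with them",  # index 6: who
        f"It happened {where}",                   # index 7: where
        f"The grown-up {what}",                   # index 8: what
        f"They remember clearly that {who} {what} {where}",  # index 9: confirmation
    ]
    return lead_in + tail


def make_default_bank(seed: int, n_keywords: int = 5, answers_per_keyword: int = 2) -> ScenarioBank:
    """Generate the 16-scenario factorial bank (2 per age x gender x abuse cell).

    Texts are neutral English templates; the draw is deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    scenarios: list[AvatarScenario] = []
    for age, gender, abused in product(AGES, GENDERS, (True, False)):
        for replicate in (1, 2):
            sid = f"av-{age}-{gender[0]}-{'abuse' if abused else 'noabuse'}-{replicate}"
            who = str(rng.choice(_SUSPECTS))
            where = str(rng.choice(_PLACES))
            what = str(rng.choice(_ABUSE_ACTS if abused else _INNOCENT_ACTS))
            relevant = [
                Detail.make(i + 1, "relevant", text)
                for i, text in enumerate(_relevant_texts(rng, abused, who, where, what))
            ]
            topics = rng.choice(_NEUTRAL_TOPICS, size=N_DETAILS_PER_CATEGORY, replace=False)
            neutral = [
                Detail.make(i + 1, "neutral", f"They talked happily about {topic}")
                for i, topic in enumerate(topics)
            ]
            kws = rng.choice(_KEYWORDS, size=min(n_keywords, len(_KEYWORDS)), replace=False)
            side = SideDetailBank(
                entries={
                    str(kw): [
                        f"About {kw}: side answer {j + 1} for {sid}"
                        for j in range(answers_per_keyword)
                    ]
                    for kw in kws
                }
            )
            background = (
                f"A {age}-year-old {gender} child. An allegation arose after an adult "
                f"noticed changes in the child's behaviour following regular visits "
                f"{where}."
            )
            scenarios.append(
                AvatarScenario(
                    id=sid, age=age, gender=gender, abused=abused,
                    background=background, relevant_details=relevant,
                    neutral_details=neutral, side_bank=side,
                    outcome=Outcome(who=who, where=where, what=what),
                )
            )
    return ScenarioBank(scenarios=scenarios)


# ---------------------------------------------------------------------------
# serialization (YAML; JSON files parse too since JSON is a YAML subset)

def _detail_to_dict(d: Detail) -> dict:
    return {"index": d.index, "category": d.category, "text": d.text,
            "conclusion_critical": d.conclusion_critical}


def scenario_to_dict(s: AvatarScenario) -> dict:
    return {
        "id": s.id,
        "age": s.age,
        "gender": s.gender,
        "abused": s.abused,
        "background": s.background,
        "relevant_details": [_detail_to_dict(d) for d in s.relevant_details],
        "neutral_details": [_detail_to_dict(d) for d in s.neutral_details],
        "side_bank": {k: list(v) for k, v in s.side_bank.entries.items()},
        "outcome": dataclasses.asdict(s.outcome),
    }


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ScenarioFormatError(f"{context}: missing field {key!r}")
    return mapping[key]


def scenario_from_dict(doc: dict, context: str = "scenario") -> AvatarScenario:
    if not isinstance(doc, dict):
        raise ScenarioFormatError(f"{context}: expected a mapping, got {type(doc).__name__}")
    try:
        details = {}
        for name in ("relevant_details", "neutral_details"):
            raw = _require(doc, name, context)
            if not isinstance(raw, list):
                raise ScenarioFormatError(f"{context}.{name}: expected a list")
            details[name] = [
                Detail(
                    index=int(_require(d, "index", f"{context}.{name}[{i}]")),
                    category=str(_require(d, "category", f"{context}.{name}[{i}]")),
                    text=str(_require(d, "text", f"{context}.{name}[{i}]")),
                    conclusion_critical=bool(d.get("conclusion_critical", False)),
                )
                for i, d in enumerate(raw)
            ]
        outcome_raw = doc.get("outcome", {}) or {}
        return AvatarScenario(
            id=str(_require(doc, "id", context)),
            age=int(_require(doc, "age", context)),
            gender=str(_require(doc, "gender", context)),
            abused=bool(_require(doc, "abused", context)),
            background=str(doc.get("background", "")),
            relevant_details=details["relevant_details"],
            neutral_details=details["neutral_details"],
            side_bank=SideDetailBank(
                entries={str(k): [str(a) for a in v] for k, v in (doc.get("side_bank") or {}).items()}
            ),
            outcome=Outcome(
                who=str(outcome_raw.get("who", "")),
                where=str(outcome_raw.get("where", "")),
                what=str(outcome_raw.get("what", "")),
            ),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioFormatError):
            raise
        raise ScenarioFormatError(f"{context}: {exc}") from exc


def save_scenarios(bank: ScenarioBank, path: str | Path) -> None:
    doc = {"scenarios": [scenario_to_dict(s) for s in bank.scenarios]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def load_scenarios(path: str | Path) -> ScenarioBank:
    """Load and validate a scenario bank; raise on format or invariant errors."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ScenarioFormatError(f"{path}: not parseable YAML/JSON: {exc}") from exc
    if doc is None:
        raise ScenarioFormatError(f"{path}: empty file")
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ScenarioFormatError(f"{path}: top level must be a mapping with a 'scenarios' list")
    bank = ScenarioBank(
        scenarios=[
            scenario_from_dict(raw, context=f"scenarios[{i}]")
            for i, raw in enumerate(doc["scenarios"])
        ]
    )
    violations = validate_bank(bank)
    if violations:
        raise ScenarioValidationError(
            f"{path}: {len(violations)} invariant violation(s):\n  " + "\n  ".join(violations)
        )
    return bank
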