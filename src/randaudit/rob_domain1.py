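"""Cochrane RoB 2 domain 1: bias arising from the randomization process.

Three signaling questions feed the domain judgement:

1.1  Was the allocation sequence random?
1.2  Was the allocation sequence concealed until participants were
     enrolled and assigned to interventions?
1.3  Did baseline differences between intervention groups suggest a
     problem with the randomization process?

Answers come from the closed set {yes, probably yes, probably no, no,
no information}; the mapping to {low, some concerns, high} transcribes the
published Cochrane domain-1 algorithm and is kept as an editable rule
table: failed concealment is high risk outright; adequate concealment with
a random sequence and no suggestive baseline differences is low risk;
unknown concealment combined with suggestive baseline differences is high
risk; everything else raises some concerns.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Any, FrozenSet, Sequence

__all__ = [
    "Answer",
    "Judgement",
    "RobAnswer",
    "RobDomain1Assessment",
    "Rule",
    "DEFAULT_RULES",
    "judge_randomization_bias",
    "render_rob_table",
    "parse_rob_table",
    "SIGNALING_QUESTIONS",
]


class Answer(str, enum.Enum):
    YES = "yes"
    PROBABLY_YES = "probably_yes"
    PROBABLY_NO = "probably_no"
    NO = "no"
    NO_INFORMATION = "no_information"


class Judgement(str, enum.Enum):
    LOW = "low"
    SOME_CONCERNS = "some_concerns"
    HIGH = "high"


YES_ISH: FrozenSet[Answer] = frozenset({Answer.YES, Answer.PROBABLY_YES})
NO_ISH: FrozenSet[Answer] = frozenset({Answer.NO, Answer.PROBABLY_NO})
ANY: FrozenSet[Answer] = frozenset(Answer)

SIGNALING_QUESTIONS = {
    "1.1": "Was the allocation sequence random?",
    "1.2": "Was the allocation sequence concealed until participants were enrolled and assigned to interventions?",
    "1.3": "Did baseline differences between intervention groups suggest a problem with the randomization process?",
}


@dataclass
class RobAnswer:
    value: Answer
    justification: str = ""

    @classmethod
    def of(cls, value: "RobAnswer | Answer | str", justification: str = "") -> "RobAnswer":
        if isinstance(value, RobAnswer):
            return value
        if isinstance(value, bool):  # YAML 1.1 reads bare yes/no as booleans
            value = Answer.YES if value else Answer.NO
        elif isinstance(value, str):
            value = value.strip().lower().replace(" ", "_")
        return cls(Answer(value), justification)


@dataclass(frozen=True)
class Rule:
    """First-match rule: answer sets per question -> judgement."""

    sequence_random: FrozenSet[Answer]
    allocation_concealed: FrozenSet[Answer]
    baseline_imbalance: FrozenSet[Answer]
    judgement: Judgement

    def matches(self, a1: Answer, a2: Answer, a3: Answer) -> bool:
        return a1 in self.sequence_random and a2 in self.allocation_concealed and a3 in self.baseline_imbalance


#: Transcription of the published domain-1 algorithm; the final catch-all
#: rule makes the mapping total over all 5^3 answer triples.
DEFAULT_RULES: tuple[Rule, ...] = (
    Rule(ANY, NO_ISH, ANY, Judgement.HIGH),
    Rule(YES_ISH, YES_ISH, NO_ISH, Judgement.LOW),
    Rule(ANY, frozenset({Answer.NO_INFORMATION}), YES_ISH, Judgement.HIGH),
    Rule(ANY, ANY, ANY, Judgement.SOME_CONCERNS),
)


def judge_randomization_bias(
    a1: RobAnswer | Answer | str,
    a2: RobAnswer | Answer | str,
    a3: RobAnswer | Answer | str,
    rules: Sequence[Rule] = DEFAULT_RULES,
) -> Judgement:
    """Map the three signaling answers (sequence random, allocation
    concealed, baseline imbalance suggests a problem) to the domain
    judgement via the first matching rule."""
    v1, v2, v3 = (RobAnswer.of(a).value for a in (a1, a2, a3))
    for rule in rules:
        if rule.matches(v1, v2, v3):
            return rule.judgement
    raise ValueError("rule table is not total over answer triples")  # unreachable with DEFAULT_RULES


@dataclass
class RobDomain1Assessment:
    """A complete domain-1 assessment; the judgement is derived solely from
    the three answers."""

    q_sequence_random: RobAnswer
    q_allocation_concealed: RobAnswer
    q_baseline_imbalance_suggests_problem: RobAnswer
    rules: Sequence[Rule] = field(default=DEFAULT_RULES, repr=False)

    @property
    def judgement(self) -> Judgement:
        return judge_randomization_bias(
            self.q_sequence_random,
            self.q_allocation_concealed,
            self.q_baseline_imbalance_suggests_problem,
            self.rules,
        )

    @classmethod
    def from_answers(
        cls,
        sequence_random: str | Answer,
        allocation_concealed: str | Answer,
        baseline_imbalance: str | Answer,
        justifications: Sequence[str] = ("", "", ""),
    ) -> "RobDomain1Assessment":
        return cls(
            RobAnswer.of(sequence_random, justifications[0]),
            RobAnswer.of(allocation_concealed, justifications[1]),
            RobAnswer.of(baseline_imbalance, justifications[2]),
        )


_QUESTION_FIELDS = (
    ("1.1", "q_sequence_random"),
    ("1.2", "q_allocation_concealed"),
    ("1.3", "q_baseline_imbalance_suggests_problem"),
)


def render_rob_table(assessment: RobDomain1Assessment, fmt: str = "json") -> str:
    """Deterministic rendering of the assessment (``json`` round-trips via
    :func:`parse_rob_table`; ``markdown`` mirrors the published table
    layout: question, response, remarks)."""
    if fmt == "json":
        payload: dict[str, Any] = {"domain": "randomization_process", "judgement": assessment.judgement.value}
        payload["questions"] = [
            {
                "id": qid,
                "question": SIGNALING_QUESTIONS[qid],
                "response": getattr(assessment, attr).value.value,
                "justification": getattr(assessment, attr).justification,
            }
            for qid, attr in _QUESTION_FIELDS
        ]
        return json.dumps(payload, indent=2, sort_keys=True)
    if fmt == "markdown":
        lines = [
            "| # | Signaling question | Response | Remarks |",
            "|---|---|---|---|",
        ]
        for qid, attr in _QUESTION_FIELDS:
            ans = getattr(assessment, attr)
            label = ans.value.value.replace("_", " ")
            lines.append(f"| {qid} | {SIGNALING_QUESTIONS[qid]} | {label} | {ans.justification} |")
        lines.append(f"\n**Judgement: {assessment.judgement.value.replace('_', ' ')} risk of bias**")
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}")


def parse_rob_table(text: str) -> RobDomain1Assessment:
    """Inverse of the JSON rendering: parse(render(x)) == x."""
    payload = json.loads(text)
    by_id = {q["id"]: q for q in payload["questions"]}
    answers = {
        attr: RobAnswer(Answer(by_id[qid]["response"]), by_id[qid].get("justification", ""))
        for qid, attr in _QUESTION_FIELDS
    }
    return RobDomain1Assessment(**answers)
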