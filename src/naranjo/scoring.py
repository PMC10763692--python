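"""Pure scoring: per-question points, total score, ordinal category.

The total Naranjo score is the sum of the answer weights over all ten
questions; it is then binned by the scale's thresholds into one of four
totally ordered causality categories (Doubtful < Possible < Probable <
Definite).  Everything here is deterministic integer arithmetic with no
I/O; incomplete answer vectors are an error, never silently defaulted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .scale import CategoryThresholds, ResponseOption, ScaleDefinition

__all__ = [
    "Category",
    "AnswerVector",
    "Assessment",
    "IncompleteAnswersError",
    "UnknownQuestionError",
    "score_answer",
    "total_score",
    "categorize",
    "assess",
]


class Category(enum.IntEnum):
    """Ordinal causality category; integer order matches clinical strength."""

    DOUBTFUL = 0
    POSSIBLE = 1
    PROBABLE = 2
    DEFINITE = 3

    @property
    def label(self) -> str:
        """Capitalized display label, e.g. ``"Probable"``."""
        return self.name.capitalize()

    @classmethod
    def from_label(cls, label: str) -> "Category":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown category label {label!r}") from None


class UnknownQuestionError(KeyError):
    """A question index outside the scale was referenced."""


class IncompleteAnswersError(ValueError):
    """An answer vector does not cover exactly the scale's questions."""

    def __init__(self, missing: list[int], extra: list[int]):
        self.missing = missing
        self.extra = extra
        parts = []
        if missing:
            parts.append(f"missing answers for question(s) {missing}")
        if extra:
            parts.append(f"answers for unknown question(s) {extra}")
        super().__init__("; ".join(parts))


@dataclass(frozen=True)
class AnswerVector:
    """One case's responses: question index (1..10) -> :class:`ResponseOption`."""

    answers: Mapping[int, ResponseOption]

    def __post_init__(self) -> None:
        for idx, option in self.answers.items():
            if not isinstance(option, ResponseOption):
                raise TypeError(
                    f"answer for question {idx} must be a ResponseOption, got {option!r}"
                )
        object.__setattr__(self, "answers", MappingProxyType(dict(self.answers)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnswerVector):
            return NotImplemented
        return dict(self.answers) == dict(other.answers)

    def __hash__(self) -> int:
        return hash(tuple(sorted((i, o.value) for i, o in self.answers.items())))


@dataclass(frozen=True)
class Assessment:
    """The scored result for one case.

    ``total`` always equals the sum of ``contributions`` and ``category``
    always equals ``categorize(total)`` under the originating scale — both
    are established by :func:`assess` and carried, not recomputed.
    """

    case_id: str
    contributions: Mapping[int, int]
    total: int
    category: Category
    scale_name: str
    scale_version: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "contributions", MappingProxyType(dict(self.contributions)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Assessment):
            return NotImplemented
        return (
            self.case_id == other.case_id
            and dict(self.contributions) == dict(other.contributions)
            and self.total == other.total
            and self.category == other.category
            and self.scale_name == other.scale_name
            and self.scale_version == other.scale_version
        )


def score_answer(scale: ScaleDefinition, index: int, answer: ResponseOption) -> int:
    """Points contributed by answering question ``index`` with ``answer``."""
    try:
        question = scale.question(index)
    except KeyError:
        raise UnknownQuestionError(f"scale {scale.name!r} has no question {index}") from None
    return question.weights[answer]


def total_score(scale: ScaleDefinition, answers: AnswerVector) -> int:
    """Sum of answer weights over all questions; order-independent.

    Raises :class:`IncompleteAnswersError` unless the vector covers exactly
    the scale's question indices.
    """
    expected = {q.index for q in scale.questions}
    got = set(answers.answers)
    if got != expected:
        raise IncompleteAnswersError(
            missing=sorted(expected - got), extra=sorted(got - expected)
        )
    return sum(score_answer(scale, i, option) for i, option in answers.answers.items())


def categorize(thresholds: CategoryThresholds, score: int) -> Category:
    """Bin an integer score into its causality category.

    Closed lower bounds: Definite iff ``score >= definite_min``, Probable
    iff ``probable_min <= score < definite_min``, Possible iff
    ``possible_min <= score < probable_min``, otherwise Doubtful.
    """
    if score >= thresholds.definite_min:
        return Category.DEFINITE
    if score >= thresholds.probable_min:
        return Category.PROBABLE
    if score >= thresholds.possible_min:
        return Category.POSSIBLE
    return Category.DOUBTFUL


def assess(scale: ScaleDefinition, case_id: str, answers: AnswerVector) -> Assessment:
    """Score one complete case: per-question contributions, total, category."""
    expected = {q.index for q in scale.questions}
    got = set(answers.answers)
    if got != expected:
        raise IncompleteAnswersError(
            missing=sorted(expected - got), extra=sorted(got - expected)
        )
    contributions = {
        i: score_answer(scale, i, option) for i, option in sorted(answers.answers.items())
    }
    total = sum(contributions.values())
    return Assessment(
        case_id=case_id,
        contributions=contributions,
        total=total,
        category=categorize(scale.thresholds, total),
        scale_name=scale.name,
        scale_version=scale.version,
    )
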