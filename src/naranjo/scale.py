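"""The Naranjo instrument as validated, immutable data.

The Naranjo adverse drug reaction probability scale (Naranjo et al., 1981)
is a fixed questionnaire of ten questions, each answered Yes / No / Unknown
("don't know / not done"), with an integer point value per answer.  The
summed score is binned into four ordinal causality categories by three
lower-bound thresholds.  This module encodes the instrument as data — a
:class:`ScaleDefinition` — rather than code, so the canonical scale is a
built-in constant and alternative (e.g. test) scales can be loaded from
plain YAML/JSON documents and validated against the same invariants.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Any, Mapping

import yaml

__all__ = [
    "ResponseOption",
    "Question",
    "CategoryThresholds",
    "ScaleDefinition",
    "ScaleValidationError",
    "build_naranjo_scale",
    "load_scale",
    "dump_scale",
    "load_scale_file",
    "dump_scale_file",
]


class ScaleValidationError(ValueError):
    """A scale document or component violates a structural invariant."""


class ResponseOption(enum.Enum):
    """One of the three admissible answers to a scale question."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    def __repr__(self) -> str:  # keep test output readable
        return f"ResponseOption.{self.name}"


#: Inclusive bounds on any single answer weight.
WEIGHT_MIN = -1
WEIGHT_MAX = 2

#: Number of questions in the instrument.
N_QUESTIONS = 10


@dataclass(frozen=True)
class Question:
    """A single scale question with its per-answer point weights.

    Parameters
    ----------
    index:
        1-based position in the instrument (1..10).
    text:
        The prompt shown to the assessor, verbatim from the instrument.
    weights:
        Points awarded for each :class:`ResponseOption`; integers in
        [-1, 2], total over all three options.
    """

    index: int
    text: str
    weights: Mapping[ResponseOption, int]

    def __post_init__(self) -> None:
        if not isinstance(self.index, int) or isinstance(self.index, bool):
            raise ScaleValidationError(f"question index must be an integer, got {self.index!r}")
        if not (1 <= self.index <= N_QUESTIONS):
            raise ScaleValidationError(
                f"question index must be in 1..{N_QUESTIONS}, got {self.index}"
            )
        missing = [o for o in ResponseOption if o not in self.weights]
        if missing:
            raise ScaleValidationError(
                f"question {self.index}: missing weight for option(s) "
                + ", ".join(o.name for o in missing)
            )
        extra = [k for k in self.weights if not isinstance(k, ResponseOption)]
        if extra:
            raise ScaleValidationError(
                f"question {self.index}: unknown weight key(s) {extra!r}"
            )
        for option, w in self.weights.items():
            if not isinstance(w, int) or isinstance(w, bool):
                raise ScaleValidationError(
                    f"question {self.index}: weight for {option.name} must be an "
                    f"integer, got {w!r}"
                )
            if not (WEIGHT_MIN <= w <= WEIGHT_MAX):
                raise ScaleValidationError(
                    f"question {self.index}: weight for {option.name} is {w}, "
                    f"outside [{WEIGHT_MIN}, {WEIGHT_MAX}]"
                )
        # freeze the mapping so the instrument is genuinely immutable
        object.__setattr__(self, "weights", MappingProxyType(dict(self.weights)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Question):
            return NotImplemented
        return (
            self.index == other.index
            and self.text == other.text
            and dict(self.weights) == dict(other.weights)
        )

    def __hash__(self) -> int:
        return hash((self.index, self.text, tuple(sorted((o.value, w) for o, w in self.weights.items()))))


@dataclass(frozen=True)
class CategoryThresholds:
    """Lower bounds for the three upper causality categories.

    Scores ``>= definite_min`` are Definite, ``>= probable_min`` Probable,
    ``>= possible_min`` Possible; anything below ``possible_min`` is
    Doubtful.  Three strictly ordered lower bounds partition the integers
    into four exhaustive, disjoint bins by construction.
    """

    definite_min: int
    probable_min: int
    possible_min: int

    def __post_init__(self) -> None:
        for name in ("definite_min", "probable_min", "possible_min"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ScaleValidationError(f"threshold {name} must be an integer, got {v!r}")
        if not (self.possible_min < self.probable_min < self.definite_min):
            raise ScaleValidationError(
                "thresholds must satisfy possible_min < probable_min < definite_min, "
                f"got possible_min={self.possible_min}, probable_min={self.probable_min}, "
                f"definite_min={self.definite_min}"
            )


@dataclass(frozen=True)
class ScaleDefinition:
    """A complete, validated causality-assessment instrument."""

    name: str
    version: str
    questions: tuple[Question, ...]
    thresholds: CategoryThresholds

    def __post_init__(self) -> None:
        object.__setattr__(self, "questions", tuple(self.questions))
        n = len(self.questions)
        if n != N_QUESTIONS:
            raise ScaleValidationError(
                f"scale must have exactly {N_QUESTIONS} questions, got {n}"
            )
        indices = [q.index for q in self.questions]
        if indices != list(range(1, N_QUESTIONS + 1)):
            raise ScaleValidationError(
                f"question indices must be 1..{N_QUESTIONS} in ascending order, got {indices}"
            )

    def question(self, index: int) -> Question:
        """Return the question with the given 1-based index."""
        if not (1 <= index <= len(self.questions)):
            raise KeyError(f"no question with index {index}")
        return self.questions[index - 1]


# Table of the canonical instrument: (text, yes, no, unknown) per question.
_NARANJO_ROWS: tuple[tuple[str, int, int, int], ...] = (
    ("Are there previous conclusive reports on this reaction?", 1, 0, 0),
    ("Did the adverse reaction appear after the suspected drug was administered?", 2, -1, 0),
    (
        "Did the adverse reaction improve when the drug was discontinued or a "
        "specific antagonists was administered?",
        1, 0, 0,
    ),
    ("Did the adverse reaction reappear when the drug was readministered?", 2, -1, 0),
    ("Are there alternative causes that could on their own have caused the reaction?", -1, 2, 0),
    ("Did the reaction reappear when a placebo was given?", -1, 1, 0),
    (
        "Was the drug detected in the blood (or other fluids) in concentrations "
        "known to be toxic?",
        1, 0, 0,
    ),
    (
        "Was the reaction more severe when the dose was increased or less severe "
        "when the dose was decreased?",
        1, 0, 0,
    ),
    (
        "Did the patient have a similar reaction to the same or similar drug in "
        "any previous exposure?",
        1, 0, 0,
    ),
    ("Was the adverse event confirmed by any objective evidence?", 1, 0, 0),
)


def build_naranjo_scale() -> ScaleDefinition:
    """Construct the canonical Naranjo scale.

    Ten questions with the published per-answer weights; every "don't know"
    answer scores 0.  Thresholds: score >= 9 Definite, 5-8 Probable,
    1-4 Possible, <= 0 Doubtful.
    """
    questions = tuple(
        Question(
            index=i,
            text=text,
            weights={
                ResponseOption.YES: yes,
                ResponseOption.NO: no,
                ResponseOption.UNKNOWN: unknown,
            },
        )
        for i, (text, yes, no, unknown) in enumerate(_NARANJO_ROWS, start=1)
    )
    return ScaleDefinition(
        name="naranjo",
        version="1981",
        questions=questions,
        thresholds=CategoryThresholds(definite_min=9, probable_min=5, possible_min=1),
    )


def dump_scale(scale: ScaleDefinition) -> dict[str, Any]:
    """Serialize a scale to a plain document (inverse of :func:`load_scale`)."""
    return {
        "name": scale.name,
        "version": scale.version,
        "questions": [
            {
                "index": q.index,
                "text": q.text,
                "weights": {o.value: q.weights[o] for o in ResponseOption},
            }
            for q in scale.questions
        ],
        "thresholds": {
            "definite_min": scale.thresholds.definite_min,
            "probable_min": scale.thresholds.probable_min,
            "possible_min": scale.thresholds.possible_min,
        },
    }


def load_scale(document: Mapping[str, Any]) -> ScaleDefinition:
    """Build a validated :class:`ScaleDefinition` from a plain document.

    The document must carry ``name``, ``version``, a ``questions`` list of
    ``{index, text, weights: {yes, no, unknown}}`` and a ``thresholds``
    mapping with the three lower bounds.  Violations raise
    :class:`ScaleValidationError` naming the offending field.
    """
    for key in ("name", "version", "questions", "thresholds"):
        if key not in document:
            raise ScaleValidationError(f"scale document missing required key {key!r}")

    raw_questions = document["questions"]
    if len(raw_questions) != N_QUESTIONS:
        raise ScaleValidationError(
            f"scale document must define exactly {N_QUESTIONS} questions, "
            f"got {len(raw_questions)}"
        )
    seen: set[int] = set()
    questions = []
    for pos, rq in enumerate(raw_questions):
        for key in ("index", "text", "weights"):
            if key not in rq:
                raise ScaleValidationError(f"question at position {pos}: missing key {key!r}")
        idx = rq["index"]
        if idx in seen:
            raise ScaleValidationError(f"duplicate question index {idx}")
        seen.add(idx)
        raw_w = rq["weights"]
        weights: dict[ResponseOption, int] = {}
        for option in ResponseOption:
            if option.value not in raw_w:
                raise ScaleValidationError(
                    f"question {idx}: weights missing option {option.value!r}"
                )
            weights[option] = raw_w[option.value]
        questions.append(Question(index=idx, text=rq["text"], weights=weights))

    raw_t = document["thresholds"]
    for key in ("definite_min", "probable_min", "possible_min"):
        if key not in raw_t:
            raise ScaleValidationError(f"thresholds missing key {key!r}")
    thresholds = CategoryThresholds(
        definite_min=raw_t["definite_min"],
        probable_min=raw_t["probable_min"],
        possible_min=raw_t["possible_min"],
    )
    questions.sort(key=lambda q: q.index)
    return ScaleDefinition(
        name=document["name"],
        version=document["version"],
        questions=tuple(questions),
        thresholds=thresholds,
    )


def load_scale_file(path: str | Path) -> ScaleDefinition:
    """Load a scale from a UTF-8 YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        document = json.loads(text)
    else:
        document = yaml.safe_load(text)
    if not isinstance(document, Mapping):
        raise ScaleValidationError(f"{path}: scale document must be a mapping")
    return load_scale(document)


def dump_scale_file(scale: ScaleDefinition, path: str | Path) -> None:
    """Write a scale document as UTF-8 YAML or JSON (by extension)."""
    path = Path(path)
    document = dump_scale(scale)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(document, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(document, sort_keys=False), encoding="utf-8")
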