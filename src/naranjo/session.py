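"""Interactive console workflow: prompt, validate, re-prompt, summarize.

Reproduces the assessment-console loop: each question is asked in order,
the operator answers with a short token ('Y', 'N', 'X' by default),
invalid tokens trigger an explanatory re-prompt of the same question with
unbounded retries, and a completed run prints the total score and its
category.  Every line consumed is recorded in a :class:`SessionTranscript`
so a run can be audited or replayed; identical scripted input always
yields byte-identical output.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO

from .scale import ResponseOption, ScaleDefinition
from .scoring import AnswerVector, Assessment, assess

__all__ = [
    "TokenDialect",
    "DEFAULT_DIALECT",
    "Rejection",
    "ABORT",
    "EventOutcome",
    "SessionEvent",
    "SessionTranscript",
    "parse_token",
    "run_session",
    "transcript_to_dict",
    "write_transcript",
]


def _canon(token: str) -> str:
    return token.strip().casefold()


@dataclass(frozen=True)
class TokenDialect:
    """Accepted input tokens for each response, plus abort tokens.

    Tokens are canonicalized (whitespace-trimmed, case-folded) before
    comparison; the four canonical sets must be pairwise disjoint.
    """

    yes_tokens: frozenset[str]
    no_tokens: frozenset[str]
    unknown_tokens: frozenset[str]
    abort_tokens: frozenset[str]

    def __post_init__(self) -> None:
        sets = {
            "yes_tokens": frozenset(_canon(t) for t in self.yes_tokens),
            "no_tokens": frozenset(_canon(t) for t in self.no_tokens),
            "unknown_tokens": frozenset(_canon(t) for t in self.unknown_tokens),
            "abort_tokens": frozenset(_canon(t) for t in self.abort_tokens),
        }
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValueError(
                        f"token sets {a} and {b} overlap after canonicalization: "
                        f"{sorted(overlap)}"
                    )
        for name, canon in sets.items():
            object.__setattr__(self, name, canon)

    def help_text(self) -> str:
        """One-line reminder of the accepted tokens."""
        def show(tokens: frozenset[str]) -> str:
            return "/".join(sorted(tokens, key=lambda t: (len(t), t)))

        return (
            f"Please answer {show(self.yes_tokens)} (yes), "
            f"{show(self.no_tokens)} (no), "
            f"{show(self.unknown_tokens)} (unknown), "
            f"or {show(self.abort_tokens)} to abort."
        )


#: Default dialect: the instrument's single-letter tokens plus full words,
#: and "quit" as a clean mid-session exit.
DEFAULT_DIALECT = TokenDialect(
    yes_tokens=frozenset({"y", "yes"}),
    no_tokens=frozenset({"n", "no"}),
    unknown_tokens=frozenset({"x", "unknown"}),
    abort_tokens=frozenset({"quit"}),
)


@dataclass(frozen=True)
class Rejection:
    """An input token outside every accepted set; carries the help message."""

    raw: str
    message: str


class _AbortSignal:
    """Sentinel for an operator-requested abort."""

    def __repr__(self) -> str:
        return "ABORT"


ABORT = _AbortSignal()


def parse_token(
    dialect: TokenDialect, raw: str
) -> ResponseOption | _AbortSignal | Rejection:
    """Classify one raw input line as an answer, an abort, or a rejection."""
    token = _canon(raw)
    if token in dialect.yes_tokens:
        return ResponseOption.YES
    if token in dialect.no_tokens:
        return ResponseOption.NO
    if token in dialect.unknown_tokens:
        return ResponseOption.UNKNOWN
    if token in dialect.abort_tokens:
        return ABORT
    return Rejection(raw=raw, message=dialect.help_text())


class EventOutcome(enum.Enum):
    ACCEPTED = "accepted"
    REJECTED = "rejected"
    ABORTED = "aborted"


@dataclass(frozen=True)
class SessionEvent:
    """One consumed input line: which question, what was typed, what happened."""

    question_index: int
    raw: str
    outcome: EventOutcome
    option: Optional[ResponseOption] = None


@dataclass
class SessionTranscript:
    """Ordered audit log of one interactive run.

    ``result`` is present iff every question received an accepted answer.
    """

    events: list[SessionEvent] = field(default_factory=list)
    result: Optional[Assessment] = None

    @property
    def completed(self) -> bool:
        return self.result is not None

    def accepted_answers(self) -> dict[int, ResponseOption]:
        return {
            e.question_index: e.option
            for e in self.events
            if e.outcome is EventOutcome.ACCEPTED and e.option is not None
        }


def run_session(
    scale: ScaleDefinition,
    input_stream: TextIO,
    output_stream: TextIO,
    dialect: TokenDialect = DEFAULT_DIALECT,
    case_id: str = "interactive",
) -> SessionTranscript:
    """Run the console assessment loop over line-oriented streams.

    Questions are asked in index order; a rejected token re-prompts the
    same question (unbounded retries).  End of input before completion, or
    an abort token, yields an aborted transcript with no result.  On
    completion the final score and category are written to the output
    stream and the transcript carries the :class:`Assessment`.
    """
    transcript = SessionTranscript()
    output_stream.write(f"ADR causality assessment — scale: {scale.name} v{scale.version}\n")
    for question in scale.questions:
        prompt = f"Q{question.index}. {question.text} [Y/N/X]: "
        while True:
            output_stream.write(prompt)
            line = input_stream.readline()
            if line == "":  # end of input: forced exit
                transcript.events.append(
                    SessionEvent(question.index, "", EventOutcome.ABORTED)
                )
                output_stream.write("\n[session aborted: end of input]\n")
                return transcript
            raw = line.rstrip("\n")
            parsed = parse_token(dialect, raw)
            if isinstance(parsed, Rejection):
                transcript.events.append(
                    SessionEvent(question.index, raw, EventOutcome.REJECTED)
                )
                output_stream.write(f"Invalid input {raw.strip()!r}. {parsed.message}\n")
                continue
            if parsed is ABORT:
                transcript.events.append(
                    SessionEvent(question.index, raw, EventOutcome.ABORTED)
                )
                output_stream.write("[session aborted by operator]\n")
                return transcript
            assert isinstance(parsed, ResponseOption)
            transcript.events.append(
                SessionEvent(question.index, raw, EventOutcome.ACCEPTED, option=parsed)
            )
            break

    answers = AnswerVector(transcript.accepted_answers())
    assessment = assess(scale, case_id, answers)
    transcript.result = assessment
    output_stream.write(
        "\n"
        "----------------------------------------\n"
        f"Naranjo score: {assessment.total}\n"
        f"ADR causality: {assessment.category.label}\n"
        "----------------------------------------\n"
    )
    return transcript


def transcript_to_dict(transcript: SessionTranscript) -> dict:
    """JSON-ready representation of a transcript (events + optional result)."""
    doc: dict = {
        "events": [
            {
                "question_index": e.question_index,
                "raw": e.raw,
                "outcome": e.outcome.value,
                "option": e.option.value if e.option is not None else None,
            }
            for e in transcript.events
        ],
        "result": None,
    }
    if transcript.result is not None:
        a = transcript.result
        doc["result"] = {
            "case_id": a.case_id,
            "contributions": {str(i): p for i, p in sorted(a.contributions.items())},
            "total": a.total,
            "category": a.category.label,
            "scale_name": a.scale_name,
            "scale_version": a.scale_version,
        }
    return doc


def write_transcript(transcript: SessionTranscript, path: str | Path) -> None:
    """Write a transcript as pretty-printed UTF-8 JSON."""
    Path(path).write_text(
        json.dumps(transcript_to_dict(transcript), indent=2) + "\n", encoding="utf-8"
    )
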