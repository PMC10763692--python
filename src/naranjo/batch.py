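"""Batch scoring: many cases from CSV/JSON files, per-case results + summary.

A batch file holds one case per record — a case id plus ten answer tokens
in the same dialect the console accepts (Y/N/X or full words).  Reading is
lenient by default: a malformed row becomes a per-row error entry rather
than killing the batch (``strict=True`` escalates to an exception), so the
conservation invariant |input cases| = |assessments| + |errors| holds for
every report.  Structural problems — a bad header, a duplicate case id —
are always hard errors.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .scale import ResponseOption, ScaleDefinition
from .scoring import (
    AnswerVector,
    Assessment,
    Category,
    IncompleteAnswersError,
    assess,
)
from .session import DEFAULT_DIALECT, Rejection, TokenDialect, parse_token

__all__ = [
    "CaseBatch",
    "BatchReport",
    "RowError",
    "BatchFormatError",
    "read_cases",
    "write_cases",
    "score_batch",
    "write_report",
    "summary_to_dict",
]

N_QUESTIONS = 10
CSV_CASE_HEADER = ["case_id"] + [f"q{i}" for i in range(1, N_QUESTIONS + 1)]
CSV_REPORT_HEADER = (
    ["case_id", "total_score", "category"]
    + [f"q{i}_points" for i in range(1, N_QUESTIONS + 1)]
)


class BatchFormatError(ValueError):
    """A batch file is structurally unusable (header, duplicate ids, ...)."""


@dataclass(frozen=True)
class RowError:
    """A per-record problem: which case/row, and what was wrong."""

    ref: str  # case_id if known, else "row N"
    message: str


@dataclass
class CaseBatch:
    """An ordered collection of identified cases, with any rows that failed to parse."""

    cases: list[tuple[str, AnswerVector]]
    source: str = ""
    row_errors: list[RowError] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case_id, _ in self.cases:
            if case_id in seen:
                raise BatchFormatError(f"duplicate case_id {case_id!r}")
            seen.add(case_id)

    def __len__(self) -> int:
        return len(self.cases)


@dataclass
class BatchReport:
    """Per-case assessments, a category tally, and per-row errors."""

    assessments: list[Assessment]
    counts: dict[Category, int]
    errors: list[RowError]


def _parse_answer_token(
    dialect: TokenDialect, raw: str
) -> ResponseOption | Rejection:
    parsed = parse_token(dialect, raw)
    if isinstance(parsed, ResponseOption):
        return parsed
    # abort tokens make no sense in a file cell; treat like any invalid token
    return Rejection(raw=raw, message=f"invalid answer token {raw!r}")


def _row_to_vector(
    dialect: TokenDialect, tokens: Sequence[str]
) -> AnswerVector | str:
    """Parse ten answer cells; return a vector or an error message."""
    if len(tokens) != N_QUESTIONS:
        return f"expected {N_QUESTIONS} answer cells, got {len(tokens)}"
    answers: dict[int, ResponseOption] = {}
    bad: list[str] = []
    for i, cell in enumerate(tokens, start=1):
        parsed = _parse_answer_token(dialect, cell)
        if isinstance(parsed, Rejection):
            bad.append(f"q{i}={cell!r}")
        else:
            answers[i] = parsed
    if bad:
        return "invalid answer token(s): " + ", ".join(bad)
    return AnswerVector(answers)


def read_cases(
    path: str | Path,
    format: str,
    dialect: TokenDialect = DEFAULT_DIALECT,
    strict: bool = False,
) -> CaseBatch:
    """Read a batch of cases from a CSV or JSON file.

    CSV: header ``case_id,q1,...,q10``; cells are dialect tokens.
    JSON: a list of ``{"case_id": ..., "answers": {"1": ..., "10": ...}}``.
    Malformed rows become :class:`RowError` entries on the returned batch
    (or raise :class:`BatchFormatError` when ``strict``); a bad header or a
    duplicate case id always raises.
    """
    path = Path(path)
    if format == "csv":
        batch = _read_csv(path, dialect)
    elif format == "json":
        batch = _read_json(path, dialect)
    else:
        raise ValueError(f"unknown batch format {format!r} (expected 'csv' or 'json')")
    if strict and batch.row_errors:
        first = batch.row_errors[0]
        raise BatchFormatError(
            f"{path}: {len(batch.row_errors)} malformed row(s) in strict mode; "
            f"first: {first.ref}: {first.message}"
        )
    return batch


def _read_csv(path: Path, dialect: TokenDialect) -> CaseBatch:
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise BatchFormatError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != CSV_CASE_HEADER:
            raise BatchFormatError(
                f"{path}: bad header {header!r}, expected {','.join(CSV_CASE_HEADER)}"
            )
        cases: list[tuple[str, AnswerVector]] = []
        errors: list[RowError] = []
        seen: set[str] = set()
        for row_num, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue  # blank line
            case_id = row[0].strip()
            ref = case_id or f"row {row_num}"
            if case_id and case_id in seen:
                raise BatchFormatError(f"{path}: duplicate case_id {case_id!r}")
            if case_id:
                seen.add(case_id)
            if not case_id:
                errors.append(RowError(ref=f"row {row_num}", message="empty case_id"))
                continue
            result = _row_to_vector(dialect, row[1:])
            if isinstance(result, str):
                errors.append(RowError(ref=ref, message=result))
            else:
                cases.append((case_id, result))
    return CaseBatch(cases=cases, source=str(path), row_errors=errors)


def _read_json(path: Path, dialect: TokenDialect) -> CaseBatch:
    with path.open(encoding="utf-8") as handle:
        try:
            records = json.load(handle)
        except json.JSONDecodeError as exc:
            raise BatchFormatError(f"{path}: invalid JSON: {exc}") from None
    if not isinstance(records, list):
        raise BatchFormatError(f"{path}: expected a JSON list of case records")
    cases: list[tuple[str, AnswerVector]] = []
    errors: list[RowError] = []
    seen: set[str] = set()
    for pos, record in enumerate(records):
        ref = f"record {pos}"
        if not isinstance(record, dict) or "case_id" not in record:
            errors.append(RowError(ref=ref, message="record missing case_id"))
            continue
        case_id = str(record["case_id"])
        ref = case_id
        if case_id in seen:
            raise BatchFormatError(f"{path}: duplicate case_id {case_id!r}")
        seen.add(case_id)
        raw_answers = record.get("answers")
        if not isinstance(raw_answers, dict):
            errors.append(RowError(ref=ref, message="record missing answers mapping"))
            continue
        tokens = []
        missing = [str(i) for i in range(1, N_QUESTIONS + 1) if str(i) not in raw_answers]
        if missing:
            errors.append(
                RowError(ref=ref, message=f"missing answers for question(s) {missing}")
            )
            continue
        for i in range(1, N_QUESTIONS + 1):
            tokens.append(str(raw_answers[str(i)]))
        result = _row_to_vector(dialect, tokens)
        if isinstance(result, str):
            errors.append(RowError(ref=ref, message=result))
        else:
            cases.append((case_id, result))
    return CaseBatch(cases=cases, source=str(path), row_errors=errors)


_OPTION_TOKEN = {
    ResponseOption.YES: "Y",
    ResponseOption.NO: "N",
    ResponseOption.UNKNOWN: "X",
}


def write_cases(batch: CaseBatch, path: str | Path, format: str) -> None:
    """Write a batch's valid cases back to disk; inverse of :func:`read_cases`."""
    path = Path(path)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_CASE_HEADER)
        for case_id, vector in batch.cases:
            row = [case_id] + [
                _OPTION_TOKEN[vector.answers[i]] for i in range(1, N_QUESTIONS + 1)
            ]
            writer.writerow(row)
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif format == "json":
        records = [
            {
                "case_id": case_id,
                "answers": {
                    str(i): vector.answers[i].value for i in range(1, N_QUESTIONS + 1)
                },
            }
            for case_id, vector in batch.cases
        ]
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown batch format {format!r} (expected 'csv' or 'json')")


def score_batch(scale: ScaleDefinition, batch: CaseBatch) -> BatchReport:
    """Assess every valid case; tally categories; carry forward row errors.

    Input order is preserved; per-case scoring failures (e.g. an incomplete
    vector built through the API) become report errors, never exceptions.
    """
    assessments: list[Assessment] = []
    errors: list[RowError] = list(batch.row_errors)
    counts: dict[Category, int] = {c: 0 for c in Category}
    for case_id, vector in batch.cases:
        try:
            a = assess(scale, case_id, vector)
        except IncompleteAnswersError as exc:
            errors.append(RowError(ref=case_id, message=str(exc)))
            continue
        assessments.append(a)
        counts[a.category] += 1
    return BatchReport(assessments=assessments, counts=counts, errors=errors)


def summary_to_dict(report: BatchReport) -> dict:
    """Category tally and error count as a JSON-ready mapping."""
    return {
        "counts": {c.label: report.counts[c] for c in Category},
        "n_assessed": len(report.assessments),
        "n_errors": len(report.errors),
    }


def write_report(
    report: BatchReport,
    path: str | Path,
    format: str,
    summary_path: Optional[str | Path] = None,
) -> None:
    """Write per-case results as CSV or JSON; byte-stable for equal inputs.

    CSV columns: ``case_id,total_score,category,q1_points,...,q10_points``;
    the category tally goes to ``summary_path`` (JSON) when given.  The
    JSON format embeds assessments, the summary block, and errors in one
    document.
    """
    path = Path(path)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_REPORT_HEADER)
        for a in report.assessments:
            writer.writerow(
                [a.case_id, a.total, a.category.label]
                + [a.contributions[i] for i in range(1, N_QUESTIONS + 1)]
            )
        path.write_text(buf.getvalue(), encoding="utf-8")
        if summary_path is not None:
            Path(summary_path).write_text(
                json.dumps(summary_to_dict(report), indent=2) + "\n", encoding="utf-8"
            )
    elif format == "json":
        doc = {
            "assessments": [
                {
                    "case_id": a.case_id,
                    "total_score": a.total,
                    "category": a.category.label,
                    "contributions": {
                        str(i): a.contributions[i] for i in range(1, N_QUESTIONS + 1)
                    },
                    "scale_name": a.scale_name,
                    "scale_version": a.scale_version,
                }
                for a in report.assessments
            ],
            "summary": summary_to_dict(report),
            "errors": [{"ref": e.ref, "message": e.message} for e in report.errors],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        if summary_path is not None:
            Path(summary_path).write_text(
                json.dumps(summary_to_dict(report), indent=2) + "\n", encoding="utf-8"
            )
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'csv' or 'json')")
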