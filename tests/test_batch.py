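"""Batch file I/O, per-row error capture, and report serialization."""

import json

import pytest

from naranjo import (
    BatchFormatError,
    CaseBatch,
    Category,
    ResponseOption,
    read_cases,
    score_batch,
    write_cases,
    write_report,
)
from tests.conftest import make_vector

Y, N, X = ResponseOption.YES, ResponseOption.NO, ResponseOption.UNKNOWN


def write_csv(path, rows, header="case_id,q1,q2,q3,q4,q5,q6,q7,q8,q9,q10"):
    path.write_text(header + "\n" + "".join(r + "\n" for r in rows), encoding="utf-8")


def test_read_csv_all_unknown_row(tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,X,X,X,X,X,X,X,X,X,X"])
    batch = read_cases(path, format="csv")
    assert len(batch) == 1
    case_id, vector = batch.cases[0]
    assert case_id == "c1"
    assert all(vector.answers[i] is X for i in range(1, 11))


def test_read_csv_accepts_full_words_and_case(tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,yes,NO,Unknown,y,n,x,Y,N,X,yes"])
    batch = read_cases(path, format="csv")
    (_, vector), = batch.cases
    assert vector.answers[1] is Y
    assert vector.answers[2] is N
    assert vector.answers[3] is X


def test_invalid_token_becomes_row_error_not_failure(tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,Y,Y,?,N,X,X,X,X,X,X", "c2,X,X,X,X,X,X,X,X,X,X"])
    batch = read_cases(path, format="csv")
    assert len(batch) == 1
    assert len(batch.row_errors) == 1
    assert batch.row_errors[0].ref == "c1"
    assert "q3" in batch.row_errors[0].message


def test_strict_mode_escalates_row_errors(tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,Y,Y,?,N,X,X,X,X,X,X"])
    with pytest.raises(BatchFormatError, match="strict"):
        read_cases(path, format="csv", strict=True)


def test_bad_header_is_format_error(tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,X,X,X,X,X,X,X,X,X,X"], header="id,q1,q2,q3,q4,q5,q6,q7,q8,q9,q10")
    with pytest.raises(BatchFormatError, match="header"):
        read_cases(path, format="csv")


def test_duplicate_case_id_is_format_error(tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,X,X,X,X,X,X,X,X,X,X", "c1,Y,X,X,X,X,X,X,X,X,X"])
    with pytest.raises(BatchFormatError, match="duplicate case_id"):
        read_cases(path, format="csv")


def test_json_round_trip_preserves_cases(tmp_path):
    batch = CaseBatch(
        cases=[("a", make_vector(q1=Y, q5=N)), ("b", make_vector(default=Y))],
        source="test",
    )
    path = tmp_path / "cases.json"
    write_cases(batch, path, format="json")
    again = read_cases(path, format="json")
    assert again.cases == batch.cases


def test_csv_round_trip_preserves_cases(tmp_path):
    batch = CaseBatch(cases=[("a", make_vector(q2=N)), ("b", make_vector())], source="t")
    path = tmp_path / "cases.csv"
    write_cases(batch, path, format="csv")
    assert read_cases(path, format="csv").cases == batch.cases


def test_json_missing_answers_is_row_error(tmp_path):
    path = tmp_path / "cases.json"
    path.write_text(json.dumps([{"case_id": "c1", "answers": {"1": "Y"}}]))
    batch = read_cases(path, format="json")
    assert len(batch) == 0
    assert len(batch.row_errors) == 1
    assert "missing answers" in batch.row_errors[0].message


def test_score_batch_counts_by_category(naranjo_scale, all_unknown, max_vector, min_vector):
    """The three canonical example vectors (totals 0, 13, -4) tally 2 Doubtful + 1 Definite."""
    batch = CaseBatch(
        cases=[("c1", all_unknown), ("c2", max_vector), ("c3", min_vector)], source="t"
    )
    report = score_batch(naranjo_scale, batch)
    assert report.counts == {
        Category.DOUBTFUL: 2,
        Category.POSSIBLE: 0,
        Category.PROBABLE: 0,
        Category.DEFINITE: 1,
    }
    assert [a.total for a in report.assessments] == [0, 13, -4]


def test_empty_batch_gives_empty_report(naranjo_scale):
    report = score_batch(naranjo_scale, CaseBatch(cases=[], source="t"))
    assert report.assessments == []
    assert all(v == 0 for v in report.counts.values())
    assert report.errors == []


def test_conservation_with_mixed_rows(naranjo_scale, tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,Y,Y,?,N,X,X,X,X,X,X", "c2,X,X,X,X,X,X,X,X,X,X"])
    batch = read_cases(path, format="csv")
    report = score_batch(naranjo_scale, batch)
    assert len(report.assessments) + len(report.errors) == 2
    assert sum(report.counts.values()) == len(report.assessments)


def test_copies_of_one_case_score_identically(naranjo_scale, max_vector):
    batch = CaseBatch(cases=[(f"c{i}", max_vector) for i in range(20)], source="t")
    report = score_batch(naranjo_scale, batch)
    assert len({(a.total, a.category) for a in report.assessments}) == 1


def test_report_csv_row_for_all_unknown_case(naranjo_scale, all_unknown, tmp_path):
    batch = CaseBatch(cases=[("c1", all_unknown)], source="t")
    report = score_batch(naranjo_scale, batch)
    path = tmp_path / "report.csv"
    write_report(report, path, format="csv")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("case_id,total_score,category,q1_points")
    assert lines[1] == "c1,0,Doubtful,0,0,0,0,0,0,0,0,0,0"


def test_empty_report_is_header_only(naranjo_scale, tmp_path):
    report = score_batch(naranjo_scale, CaseBatch(cases=[], source="t"))
    path = tmp_path / "report.csv"
    write_report(report, path, format="csv")
    assert path.read_text().splitlines() == [
        "case_id,total_score,category,"
        + ",".join(f"q{i}_points" for i in range(1, 11))
    ]


def test_report_writes_are_byte_stable(naranjo_scale, max_vector, min_vector, tmp_path):
    batch = CaseBatch(cases=[("a", max_vector), ("b", min_vector)], source="t")
    report = score_batch(naranjo_scale, batch)
    p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
    write_report(report, p1, format="json", summary_path=tmp_path / "s1.json")
    write_report(report, p2, format="json", summary_path=tmp_path / "s2.json")
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "s1.json").read_bytes() == (tmp_path / "s2.json").read_bytes()


def test_report_json_carries_summary_and_errors(naranjo_scale, tmp_path):
    path = tmp_path / "cases.csv"
    write_csv(path, ["c1,Y,Y,?,N,X,X,X,X,X,X", "c2,X,X,X,X,X,X,X,X,X,X"])
    report = score_batch(naranjo_scale, read_cases(path, format="csv"))
    out = tmp_path / "report.json"
    write_report(report, out, format="json")
    doc = json.loads(out.read_text())
    assert doc["summary"]["n_assessed"] == 1
    assert doc["summary"]["n_errors"] == 1
    assert doc["summary"]["counts"]["Doubtful"] == 1
    assert doc["errors"][0]["ref"] == "c1"
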