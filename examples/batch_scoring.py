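"""Score a CSV file of cases and summarize the category distribution.

Builds a small case file (one row is deliberately malformed), scores the
batch leniently, and prints the per-case results plus the tally.  The
malformed row becomes a recorded error, not a crash.
"""

import tempfile
from pathlib import Path

from naranjo import build_naranjo_scale, read_cases, score_batch

csv_text = """\
case_id,q1,q2,q3,q4,q5,q6,q7,q8,q9,q10
rash-001,Y,Y,Y,X,N,X,X,X,N,Y
nausea-002,X,Y,N,X,Y,X,X,X,X,X
bad-row,Y,?,X,X,X,X,X,X,X,X
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cases.csv"
    path.write_text(csv_text)
    batch = read_cases(path, format="csv")

scale = build_naranjo_scale()
report = score_batch(scale, batch)

for a in report.assessments:
    print(f"{a.case_id}: score {a.total:+d} -> {a.category.label}")
for err in report.errors:
    print(f"{err.ref}: ERROR {err.message}")
print("tally:", {c.label: n for c, n in report.counts.items() if n})

# rash-001 scores 7 (Probable); nausea-002 scores 1 (Possible: temporal
# association +2, but an alternative cause subtracts a point); bad-row's
# '?' is reported, and cases in = assessments + errors.
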