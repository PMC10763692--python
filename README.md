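# naranjo-adr

A tested Python implementation of the **Naranjo adverse drug reaction (ADR)
probability scale** — the classic 10-question pharmacovigilance instrument for
judging how likely a drug caused an observed adverse event — packaged as a
library, an interactive console tool, and a batch scorer.

## The instrument

Each of the ten questions (previous reports, temporal association,
dechallenge, rechallenge, alternative causes, placebo response, toxic drug
levels, dose–response, prior similar reaction, objective confirmation) is
answered **Yes**, **No**, or **Unknown** ("don't know / not done") and
contributes an integer weight `w_q(a) ∈ {-1, 0, 1, 2}`. The total score

```
S = Σ_{q=1..10} w_q(a_q),        S ∈ [-4, 13]
```

is binned into an ordinal causality category:

| Score | Category |
|---|---|
| ≥ 9 | Definite |
| 5 – 8 | Probable |
| 1 – 4 | Possible |
| ≤ 0 | Doubtful |

Every "Unknown" weighs 0, so unanswerable questions never move the score.
The scale is modeled as immutable data (`ScaleDefinition`), with the
canonical instrument built in and a validated YAML/JSON loader for custom
variants.

## Worked example

```python
from naranjo import AnswerVector, ResponseOption, assess, build_naranjo_scale

Y, N, X = ResponseOption.YES, ResponseOption.NO, ResponseOption.UNKNOWN
scale = build_naranjo_scale()
answers = AnswerVector({1: Y, 2: Y, 3: Y, 4: X, 5: N,
                        6: X, 7: X, 8: X, 9: N, 10: Y})
result = assess(scale, case_id="rash-001", answers=answers)
print(result.total, result.category.label)
```

prints

```
7 Probable
```

A rash with prior reports (+1), clear temporal association (+2), improvement
on withdrawal (+1), no alternative cause (+2), and objective confirmation
(+1) totals 7, which falls in the 5–8 bin: the drug is a *Probable* cause.
The `examples/` directory has one short narrative script per capability
(single-case scoring, a scripted console session, batch CSV scoring,
exhaustive enumeration).

## Command line

```bash
naranjo assess --case-id rash-001 --transcript-out t.json   # interactive Y/N/X prompts
naranjo batch --in cases.csv --format csv --out report.csv --summary summary.json
naranjo fixtures --n 100 --seed 7 --out cases.csv           # synthetic batches
naranjo fixtures --enumerate --out table.csv                # all 59,049 vectors
```

The interactive session validates each token (`Y`/`N`/`X`, full words, or
`quit` to abort), re-prompts on invalid input, and prints the final score
and category. Batch mode is lenient by default — malformed rows become
recorded errors, never silent drops — and `--strict` escalates them to a
failing exit.

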