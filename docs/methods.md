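# Methods

## The model

The Naranjo scale is a deterministic weighted questionnaire. A case is an
*answer vector* `a : {1..10} → {Yes, No, Unknown}`; each question `q` has a
total weight function `w_q` over the three options with integer values in
`[-1, 2]`; the score is `S(a) = Σ w_q(a_q)` and the category is obtained by
three closed lower bounds (`possible_min=1`, `probable_min=5`,
`definite_min=9`). Representing the cut-offs as three strictly ordered
lower bounds — rather than four printed ranges — makes the four bins
exhaustive and disjoint over all integers by construction; the published
ranges ("5–8" etc.) are contiguous over integers only, so the two
representations agree everywhere integer scores can occur.

Assumptions worth stating explicitly:

- **Integer scores only.** All weights are integers and no partial credit
  or confidence weighting exists; totals are exact, so no numerical
  tolerance questions arise anywhere in the package.
- **"Don't know" and "not known or not done" are one option**, canonically
  `UNKNOWN`, always weighing 0. The instrument uses the two phrasings
  interchangeably for the single input token `X`.
- **Completeness is the caller's problem.** The scoring core raises on an
  incomplete vector (listing the missing indices) rather than defaulting
  unanswered questions to `UNKNOWN`; a silent default would change scores
  invisibly. The console flow and the batch reader both guarantee complete
  vectors before scoring.

## Scale as data

The instrument is encoded as an immutable `ScaleDefinition` (10 `Question`s
with frozen weight mappings + `CategoryThresholds`), with the canonical
scale as a built-in constant and a schema-validated YAML/JSON loader.
Modeling the scale as data keeps the canonical constant untouchable while
letting tests construct degenerate scales through the same validation path;
`load_scale`/`dump_scale` are mutual inverses on valid input.

## Console session

The interactive loop asks the questions in index order. Tokens are
canonicalized by whitespace-trimming and case-folding before lookup; the
default dialect accepts `y/yes`, `n/no`, `x/unknown`, and `quit` as an
abort. Design choices that the source workflow leaves open, decided here:

- **Case-insensitive, trimmed matching and full-word synonyms.** The
  documented tokens are only `Y`/`N`/`X`; broader tokens reduce operator
  friction and the dialect validator guarantees the four sets stay
  pairwise disjoint after canonicalization, so no ambiguity can arise.
- **An explicit abort token.** The original flow has no mid-session exit;
  a console tool needs one, and aborts are recorded distinctly in the
  transcript rather than conflated with end-of-input.
- **Unbounded retries.** An invalid token re-prompts the same question
  forever; the only forced exits are end-of-input and the abort token.

Every consumed line becomes a transcript event, the completed session's
result is produced by calling the same `assess()` the batch path uses
(the session never re-implements scoring), and identical scripted input
yields byte-identical output, which makes replay testing exact.

## Batch format and error policy

CSV uses the header `case_id,q1,...,q10` with dialect tokens as cells;
JSON is a list of `{case_id, answers: {"1": ..., "10": ...}}`. Reading is
lenient by default: a malformed row (bad token, wrong cell count, missing
answers) becomes a per-row error entry carried through to the report, so
`|input cases| = |assessments| + |errors|` holds for every batch; a
`strict` flag escalates the first malformed row to a hard failure for
audit use. Structural defects — a wrong header, a duplicate case id — are
always hard failures, because they indicate the file as a whole is not
what it claims to be. Category labels serialize as the capitalized words
`Doubtful/Possible/Probable/Definite`. Report writing is byte-stable for
identical inputs (fixed column order, fixed JSON key order, `\n` line
endings).

## Synthetic cases and the enumeration oracle

The generator draws i.i.d. answers per question under configurable option
probabilities, **uniform (1/3 each) by default**: no empirical distribution
of assessor answers exists for this instrument, so the generator stays
agnostic rather than inventing a clinical prior. Generation is seeded
(`random.Random`) and reproducible across runs and platforms. What the
synthetic batches emulate is the *shape* of real batch input — identified
cases, complete token vectors — and nothing clinical: no drug names,
narratives, or correlated answer patterns. Passing batch tests therefore
demonstrates correctness of scoring, conservation, and serialization, not
realism of case mix.

The enumeration oracle walks all `3^10 = 59,049` possible vectors and
scores each with **its own independently re-typed copy of the weight table
and its own re-statement of the category bins**, sharing no constants with
the scoring engine; agreement between the two code paths is therefore a
genuine dual-implementation cross-check, not a tautology. Enumeration
establishes that attainable totals are exactly the integers `[-4, 13]` and
provides witness vectors for every total, covering all three category
boundaries (0|1, 4|5, 8|9).

## Problem sizes and determinism

All computations are exact integer arithmetic; the only randomness is the
case generator, always driven by an explicit seed. The test suite and the
acceptance script use full enumeration (59,049 vectors, a couple of
seconds) and a 1,000-case random batch for conservation checks — sizes
chosen because they are exhaustive or comfortably large while keeping the
whole suite under a few seconds.

## Known limitations

- The instrument itself is implemented as published; no clinical
  validation, inter-rater reliability modeling, or comparison with other
  causality scales (e.g. WHO-UMC) is in scope.
- No drug-interaction awareness: each case is scored in isolation.
- Question text is English-only, carried verbatim from the instrument.
- The batch reader accepts only the documented CSV/JSON shapes; there is
  no support for pharmacovigilance exchange formats (E2B/ICSR).
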