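"""Synthetic cases and the exhaustive-enumeration oracle.

Two jobs:

* generate reproducible random answer batches (i.i.d. answers per question
  under configurable option probabilities, uniform by default) for
  stress-testing batch I/O and scoring;
* provide an *independent* brute-force oracle over all 3^10 = 59,049
  possible answer vectors.  The oracle carries its own transcription of
  the published weight table and its own threshold logic, deliberately
  sharing no constants with :mod:`naranjo.scale` or :mod:`naranjo.scoring`,
  so agreement between the two code paths is a real cross-check rather
  than a tautology.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .batch import CaseBatch
from .scale import ResponseOption, ScaleDefinition
from .scoring import AnswerVector, Category

__all__ = [
    "GeneratorConfig",
    "random_cases",
    "enumerate_all_vectors",
    "boundary_cases",
    "oracle_total",
]

_N_QUESTIONS = 10
_N_OPTIONS = 3

# Oracle copy of the published weight table, re-typed from the instrument
# row by row (yes, no, don't-know) — independent of scale._NARANJO_ROWS.
_ORACLE_WEIGHTS: dict[int, dict[ResponseOption, int]] = {
    1: {ResponseOption.YES: 1, ResponseOption.NO: 0, ResponseOption.UNKNOWN: 0},
    2: {ResponseOption.YES: 2, ResponseOption.NO: -1, ResponseOption.UNKNOWN: 0},
    3: {ResponseOption.YES: 1, ResponseOption.NO: 0, ResponseOption.UNKNOWN: 0},
    4: {ResponseOption.YES: 2, ResponseOption.NO: -1, ResponseOption.UNKNOWN: 0},
    5: {ResponseOption.YES: -1, ResponseOption.NO: 2, ResponseOption.UNKNOWN: 0},
    6: {ResponseOption.YES: -1, ResponseOption.NO: 1, ResponseOption.UNKNOWN: 0},
    7: {ResponseOption.YES: 1, ResponseOption.NO: 0, ResponseOption.UNKNOWN: 0},
    8: {ResponseOption.YES: 1, ResponseOption.NO: 0, ResponseOption.UNKNOWN: 0},
    9: {ResponseOption.YES: 1, ResponseOption.NO: 0, ResponseOption.UNKNOWN: 0},
    10: {ResponseOption.YES: 1, ResponseOption.NO: 0, ResponseOption.UNKNOWN: 0},
}


def oracle_total(answers: Mapping[int, ResponseOption]) -> int:
    """Brute-force total under the oracle's own copy of the weight table."""
    return sum(_ORACLE_WEIGHTS[i][answers[i]] for i in range(1, _N_QUESTIONS + 1))


def _oracle_category(total: int) -> Category:
    # Re-stated from the published score bins, not from scoring.categorize.
    if total >= 9:
        return Category.DEFINITE
    if 5 <= total <= 8:
        return Category.PROBABLE
    if 1 <= total <= 4:
        return Category.POSSIBLE
    return Category.DOUBTFUL


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible random-case generation settings.

    ``option_probabilities`` must cover the three response options with
    non-negative values summing to 1 (uniform 1/3 each by default — no
    empirical answer distribution exists for real ADR assessments, so the
    generator stays agnostic).
    """

    n_cases: int
    seed: int
    option_probabilities: Mapping[ResponseOption, float] = field(
        default_factory=lambda: {o: 1.0 / 3.0 for o in ResponseOption}
    )

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be positive, got {self.n_cases}")
        probs = dict(self.option_probabilities)
        missing = [o for o in ResponseOption if o not in probs]
        if missing:
            raise ValueError(
                "option_probabilities missing " + ", ".join(o.name for o in missing)
            )
        if any(p < 0 for p in probs.values()):
            raise ValueError("option probabilities must be non-negative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"option probabilities must sum to 1, got {total}")
        object.__setattr__(self, "option_probabilities", probs)


def random_cases(config: GeneratorConfig) -> CaseBatch:
    """Draw ``n_cases`` i.i.d. answer vectors; identical seed, identical batch."""
    rng = random.Random(config.seed)
    options = list(ResponseOption)
    weights = [config.option_probabilities[o] for o in options]
    width = max(4, len(str(config.n_cases)))
    cases = []
    for k in range(1, config.n_cases + 1):
        answers = {
            i: rng.choices(options, weights=weights, k=1)[0]
            for i in range(1, _N_QUESTIONS + 1)
        }
        cases.append((f"case-{k:0{width}d}", AnswerVector(answers)))
    return CaseBatch(cases=cases, source=f"random(seed={config.seed})")


def _check_shape(scale: ScaleDefinition) -> None:
    if len(scale.questions) != _N_QUESTIONS or any(
        len(q.weights) != _N_OPTIONS for q in scale.questions
    ):
        raise ValueError(
            "enumeration oracle requires a 10-question, three-option scale"
        )


def enumerate_all_vectors(
    scale: ScaleDefinition,
) -> Iterator[tuple[AnswerVector, int, Category]]:
    """Yield every possible answer vector once, with its oracle score and category.

    The stream has exactly 3^10 = 59,049 entries.  Scores and categories
    come from the oracle's own table and bins — compare them against
    :func:`naranjo.scoring.assess` to cross-check the scoring engine.
    """
    _check_shape(scale)
    options = list(ResponseOption)
    for combo in itertools.product(options, repeat=_N_QUESTIONS):
        answers = {i: combo[i - 1] for i in range(1, _N_QUESTIONS + 1)}
        total = oracle_total(answers)
        yield AnswerVector(answers), total, _oracle_category(total)


def boundary_cases(scale: ScaleDefinition) -> CaseBatch:
    """One witness vector per attainable total, found by enumeration.

    The canonical scale attains every integer total in [-4, 13], so the
    batch covers all three category boundaries (0|1, 4|5, 8|9).  Case ids
    name the total, e.g. ``total_-4`` ... ``total_13``.
    """
    _check_shape(scale)
    witnesses: dict[int, AnswerVector] = {}
    for vector, total, _ in enumerate_all_vectors(scale):
        if total not in witnesses:
            witnesses[total] = vector
    cases = [
        (f"total_{total}", witnesses[total]) for total in sorted(witnesses)
    ]
    return CaseBatch(cases=cases, source="boundary_cases")
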