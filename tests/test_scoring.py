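"""Score arithmetic, categorization thresholds, and scoring invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naranjo import (
    AnswerVector,
    Category,
    IncompleteAnswersError,
    ResponseOption,
    UnknownQuestionError,
    assess,
    categorize,
    score_answer,
    total_score,
)
from tests.conftest import make_vector

Y, N, X = ResponseOption.YES, ResponseOption.NO, ResponseOption.UNKNOWN

# Hand-summed column totals from the published table, used as the oracle
# for the homogeneous-answer vectors below.
HAND_SUMMED_YES = 1 + 2 + 1 + 2 + (-1) + (-1) + 1 + 1 + 1 + 1  # = 8
HAND_SUMMED_NO = 0 + (-1) + 0 + (-1) + 2 + 1 + 0 + 0 + 0 + 0  # = 1


@pytest.mark.parametrize(
    "index, answer, points",
    [
        (4, N, -1),
        (7, X, 0),
        (6, Y, -1),
        (2, Y, 2),
        (5, N, 2),
        (1, Y, 1),
    ],
)
def test_score_answer_weight_cells(naranjo_scale, index, answer, points):
    assert score_answer(naranjo_scale, index, answer) == points


def test_score_answer_unknown_index(naranjo_scale):
    with pytest.raises(UnknownQuestionError, match="11"):
        score_answer(naranjo_scale, 11, Y)


@pytest.mark.parametrize(
    "option, expected",
    [(X, 0), (Y, HAND_SUMMED_YES), (N, HAND_SUMMED_NO)],
)
def test_homogeneous_vectors_match_column_sums(naranjo_scale, option, expected):
    vector = AnswerVector({i: option for i in range(1, 11)})
    assert total_score(naranjo_scale, vector) == expected


def test_incomplete_vector_lists_missing_indices(naranjo_scale):
    vector = AnswerVector({i: X for i in range(1, 8)})
    with pytest.raises(IncompleteAnswersError) as exc_info:
        total_score(naranjo_scale, vector)
    assert exc_info.value.missing == [8, 9, 10]


def test_extra_index_is_rejected(naranjo_scale):
    answers = {i: X for i in range(1, 11)}
    answers[11] = X
    with pytest.raises(IncompleteAnswersError) as exc_info:
        total_score(naranjo_scale, AnswerVector(answers))
    assert exc_info.value.extra == [11]


@pytest.mark.parametrize(
    "score, category",
    [
        (9, Category.DEFINITE),
        (13, Category.DEFINITE),
        (8, Category.PROBABLE),
        (5, Category.PROBABLE),
        (4, Category.POSSIBLE),
        (1, Category.POSSIBLE),
        (0, Category.DOUBTFUL),
        (-4, Category.DOUBTFUL),
        (100, Category.DEFINITE),
        (-100, Category.DOUBTFUL),
    ],
)
def test_categorize_boundaries(naranjo_scale, score, category):
    """Category bins: >=9 Definite, 5-8 Probable, 1-4 Possible, <=0 Doubtful."""
    assert categorize(naranjo_scale.thresholds, score) is category


def test_category_ordering():
    assert Category.DOUBTFUL < Category.POSSIBLE < Category.PROBABLE < Category.DEFINITE
    assert [c.label for c in Category] == ["Doubtful", "Possible", "Probable", "Definite"]


def test_assess_all_unknown(naranjo_scale, all_unknown):
    a = assess(naranjo_scale, "c1", all_unknown)
    assert a.total == 0
    assert a.category is Category.DOUBTFUL
    assert sum(a.contributions.values()) == a.total


def test_assess_maximum_vector(naranjo_scale, max_vector):
    """YES everywhere except NO on the two reverse-keyed questions gives the global max."""
    a = assess(naranjo_scale, "c2", max_vector)
    assert a.total == 13
    assert a.category is Category.DEFINITE


def test_assess_minimum_vector(naranjo_scale, min_vector):
    a = assess(naranjo_scale, "c3", min_vector)
    assert a.total == -4
    assert a.category is Category.DOUBTFUL


def test_assess_carries_scale_identity(naranjo_scale, all_unknown):
    a = assess(naranjo_scale, "c1", all_unknown)
    assert (a.scale_name, a.scale_version) == ("naranjo", "1981")


option_st = st.sampled_from(list(ResponseOption))
vector_st = st.builds(
    AnswerVector,
    st.fixed_dictionaries({i: option_st for i in range(1, 11)}),
)


@settings(derandomize=True, max_examples=100)
@given(vector=vector_st, order_seed=st.randoms(use_true_random=False))
def test_total_is_permutation_invariant(naranjo_scale, vector, order_seed):
    """The total does not depend on answer iteration order."""
    items = list(vector.answers.items())
    order_seed.shuffle(items)
    shuffled = AnswerVector(dict(items))
    assert total_score(naranjo_scale, shuffled) == total_score(naranjo_scale, vector)


@settings(derandomize=True, max_examples=200)
@given(vector=vector_st, index=st.integers(1, 10), target=option_st)
def test_flipping_to_heavier_answer_is_monotone(naranjo_scale, vector, index, target):
    """A strictly heavier answer strictly raises the total and never lowers the category."""
    q = naranjo_scale.question(index)
    current = vector.answers[index]
    if q.weights[target] <= q.weights[current]:
        return
    flipped = AnswerVector({**dict(vector.answers), index: target})
    before = assess(naranjo_scale, "a", vector)
    after = assess(naranjo_scale, "a", flipped)
    assert after.total > before.total
    assert after.category >= before.category
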