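import pytest

from naranjo import AnswerVector, ResponseOption, build_naranjo_scale

Y, N, X = ResponseOption.YES, ResponseOption.NO, ResponseOption.UNKNOWN


@pytest.fixture(scope="session")
def naranjo_scale():
    return build_naranjo_scale()


def make_vector(default=X, **overrides):
    """Build a complete 10-answer vector; overrides keyed like q3=Y."""
    answers = {i: default for i in range(1, 11)}
    for key, option in overrides.items():
        answers[int(key.lstrip("q"))] = option
    return AnswerVector(answers)


@pytest.fixture
def all_unknown():
    return make_vector()


@pytest.fixture
def max_vector():
    # YES everywhere except 5 and 6, where NO scores higher
    return make_vector(default=Y, q5=N, q6=N)


@pytest.fixture
def min_vector():
    # NO on 2 and 4, YES on 5 and 6, UNKNOWN elsewhere
    return make_vector(q2=N, q4=N, q5=Y, q6=Y)
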