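import pytest

from ranksat import exp1_context


@pytest.fixture(scope="session")
def unimodal():
    return exp1_context("unimodal")


@pytest.fixture(scope="session")
def bimodal():
    return exp1_context("bimodal")


@pytest.fixture(scope="session")
def neg_skew():
    return exp1_context("neg_skew")


@pytest.fixture(scope="session")
def pos_skew():
    return exp1_context("pos_skew")


@pytest.fixture(scope="session")
def all_exp1_columns(unimodal, bimodal, neg_skew, pos_skew):
    return {
        "unimodal": unimodal,
        "bimodal": bimodal,
        "neg_skew": neg_skew,
        "pos_skew": pos_skew,
    }


def brute_force_relative_rank(x: float, values) -> float:
    """Pairwise-comparison oracle for the frequency value of a member ``x``:
    (wins + half-ties among the other items) / (n - 1)."""
    below = sum(1 for v in values if v < x)
    ties = sum(1 for v in values if v == x) - 1  # excluding x itself
    return (below + 0.5 * ties) / (len(values) - 1)
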