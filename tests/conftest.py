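import pytest

from prcaudit import ScoredLabels, make_tie_block_fixture, validate_scored_labels


@pytest.fixture
def d1() -> ScoredLabels:
    """Five distinctly-scored entities, 3 positives: the worked no-ties example."""
    return validate_scored_labels([0.9, 0.8, 0.7, 0.6, 0.5], [1, 1, 0, 1, 0])


@pytest.fixture
def constant_3_2() -> ScoredLabels:
    """A constant classifier: one all-tied block of 3 positives and 2 negatives."""
    return make_tie_block_fixture([(3, 2)])


@pytest.fixture
def rank_flip_pair() -> dict[str, ScoredLabels]:
    """Two classifiers whose ranking flips between linear-tie and AP recipes.

    X: one confident positive, then a 4-pos/5-neg tie block. Linear tie
    interpolation credits the chord over the block (AUPRC 0.8) while AP only
    credits the endpoint precision (0.6).
    X's straight-line value (0.8) beats Y's (~0.72), but X's AP value (0.6)
    loses to Y's (~0.68): the winner depends on the recipe.
    """
    x = make_tie_block_fixture([(1, 0), (4, 5)])
    y = make_tie_block_fixture([(1, 0), (0, 1)] * 5)
    return {"tie_heavy": x, "tie_free": y}
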