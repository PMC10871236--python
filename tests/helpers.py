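import numpy as np

from prcaudit import ScoredLabels, validate_scored_labels


def random_dataset(
    rng: np.random.Generator, max_n: int = 12, force_ties: bool = False
) -> ScoredLabels:
    """Small random ScoredLabels with at least one positive and one negative."""
    n = int(rng.integers(2, max_n + 1))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: int(rng.integers(1, n))]] = 1
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[-1] = 0
    scores = rng.random(n)
    if force_ties:
        scores = np.round(scores, 1)
    return validate_scored_labels(scores, labels)
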