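"""Synthetic score/label generators with controllable imbalance and ties.

Two generators cover the situations where AUPRC tools disagree most:

* :func:`generate` draws class-conditional Gaussian scores — negatives from
  N(0, 1), positives from N(separation, 1) — and optionally quantizes the
  pooled scores into ``n_levels`` equal-width bins. Quantization emulates
  classifiers with discrete outputs (vote counts, coarse probabilities),
  which is exactly where score ties, and hence tie-handling differences,
  arise. Only the rank structure of the scores matters to every estimator,
  so the Gaussian family is a free choice.
* :func:`make_tie_block_fixture` builds a dataset whose tie-group sequence
  is specified exactly, for constructing worked examples and adversarial
  anchor structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import ScoredLabels, validate_scored_labels

__all__ = ["GeneratorConfig", "generate", "make_tie_block_fixture"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for the Gaussian score generator.

    separation
        Location shift (in units of the unit score SD) between positive and
        negative score distributions; 0 is an uninformative classifier.
    n_levels
        If set, scores are quantized to this many equal-width levels over
        the pooled observed range, inducing tie blocks; ``1`` collapses the
        dataset to a single constant score.
    """

    n_pos: int
    n_neg: int
    separation: float = 1.0
    n_levels: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.n_neg < 0:
            raise ValueError("n_neg must be >= 0")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_levels is not None and self.n_levels < 1:
            raise ValueError("n_levels must be >= 1 when set")


def generate(config: GeneratorConfig) -> ScoredLabels:
    """Draw one dataset; deterministic given the config (including seed)."""
    rng = np.random.default_rng(config.seed)
    pos = rng.normal(loc=config.separation, scale=1.0, size=config.n_pos)
    neg = rng.normal(loc=0.0, scale=1.0, size=config.n_neg)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=np.int64), np.zeros(config.n_neg, dtype=np.int64)]
    )
    if config.n_levels is not None:
        scores = _quantize(scores, config.n_levels)
    perm = rng.permutation(len(scores))
    return ScoredLabels(scores=scores[perm], labels=labels[perm])


def _quantize(scores: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width binning over the pooled range; scores become bin centers."""
    lo, hi = scores.min(), scores.max()
    if n_levels == 1 or lo == hi:
        return np.full_like(scores, (lo + hi) / 2)
    edges = np.linspace(lo, hi, n_levels + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_levels - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers[idx]


def make_tie_block_fixture(blocks: list[tuple[int, int]]) -> ScoredLabels:
    """Build a dataset whose tie groups are exactly ``blocks``.

    ``blocks`` lists (n_pos, n_neg) per tie group, in descending-score
    order; block k receives the synthetic score ``len(blocks) - k`` so the
    groups are strictly decreasing. Within a block, positives come before
    negatives in row order (the convention used when feeding real
    submissions to order-sensitive tools).
    """
    if not blocks:
        raise ValueError("empty block spec")
    scores: list[float] = []
    labels: list[int] = []
    n_blocks = len(blocks)
    for k, (b, c) in enumerate(blocks):
        if b < 0 or c < 0 or b + c == 0:
            raise ValueError(f"block {k}: counts must be >= 0 and sum >= 1")
        score = float(n_blocks - k)
        scores.extend([score] * (b + c))
        labels.extend([1] * b + [0] * c)
    return validate_scored_labels(scores, labels)
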