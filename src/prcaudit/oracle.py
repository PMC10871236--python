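"""Independent brute-force references for the estimators.

These are deliberately naive — enumeration, composite quadrature, pairwise
counting — so the test suite can check the closed-form implementations
against something with no shared code path. Exact rational arithmetic is
used wherever the quantities are rational so equality assertions are
bit-safe. Nothing here is performance-tuned; exhaustive enumeration is
exponential by design and guarded by a combination-count cap.

The permutation average also quantifies the gap between the two candidate
"expected coordinate" conventions for tie blocks: the linear-fp surrogate
E'[fp | tp = s] = s·c/b used by the estimators, and the combinatorial
expectation over random orderings, E[fp | tp = s] = s·c/(b+1). The two agree
at the block's endpoints but differ in the interior; both are reported so
the difference can be inspected rather than asserted away.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .anchors import ScoredLabels
from .errors import NoNegativesError, NoPositivesError
from .interpolation import Segment

__all__ = [
    "PermutationAverage",
    "permutation_average",
    "quadrature_segment_area",
    "mann_whitney_auroc",
]

_EXHAUSTIVE_CAP = 10**5


@dataclass(frozen=True)
class PermutationAverage:
    """Averages over orderings of one tie block appended to a fixed prefix."""

    b: int
    c: int
    expected_fp_at_tp: tuple[Fraction, ...]  # index s-1 holds E[fp | tp = s], s = 1..b
    expected_step_auprc: Fraction  # mean step-curve (AP) area of the block
    n_orderings: int
    exhaustive: bool

    @property
    def linear_fp_at_tp(self) -> tuple[Fraction, ...]:
        """The linear-fp surrogate s·c/b at the same s values, for comparison."""
        return tuple(Fraction(s * self.c, self.b) for s in range(1, self.b + 1))


def _block_step_area(order: tuple[int, ...], tp0: int, fp0: int, P: int) -> Fraction:
    """Step-curve (AP) area contributed by one ordering of the block."""
    tp, fp = tp0, fp0
    area = Fraction(0)
    for lab in order:
        if lab == 1:
            tp += 1
            area += Fraction(1, P) * Fraction(tp, tp + fp)
        else:
            fp += 1
    return area


def permutation_average(
    b: int,
    c: int,
    context: tuple[int, int, int] = (0, 0, None),
    mode: str = "exhaustive",
    seed: int | None = None,
    n_samples: int = 10_000,
) -> PermutationAverage:
    """Average tie-block quantities over orderings of b positives and c negatives.

    ``context`` is (tp_prefix, fp_prefix, P); ``P`` defaults to
    tp_prefix + b. Exhaustive mode enumerates all C(b+c, c) distinct label
    orderings (capped at 1e5); sampled mode shuffles with an explicit seed.
    """
    tp0, fp0, P = context
    if P is None:
        P = tp0 + b
    if b + c < 1:
        raise ValueError("empty tie block")
    if mode == "exhaustive":
        n_orderings = math.comb(b + c, c)
        if n_orderings > _EXHAUSTIVE_CAP:
            raise ValueError(
                f"C({b + c},{c}) = {n_orderings} orderings exceeds the exhaustive cap"
            )
        orders = [
            tuple(1 if i in pos else 0 for i in range(b + c))
            for pos in itertools.combinations(range(b + c), b)
        ]
    elif mode == "sampled":
        if seed is None:
            raise ValueError("sampled mode requires an explicit seed")
        rng = random.Random(seed)
        base = [1] * b + [0] * c
        orders = []
        for _ in range(n_samples):
            rng.shuffle(base)
            orders.append(tuple(base))
        n_orderings = n_samples
    else:
        raise ValueError(f"unknown mode: {mode}")

    fp_sums = [Fraction(0)] * b
    area_sum = Fraction(0)
    for order in orders:
        fp = 0
        tp = 0
        for lab in order:
            if lab == 1:
                tp += 1
                fp_sums[tp - 1] += fp
            else:
                fp += 1
        area_sum += _block_step_area(order, tp0, fp0, P)
    n = len(orders)
    return PermutationAverage(
        b=b,
        c=c,
        expected_fp_at_tp=tuple(s / n for s in fp_sums),
        expected_step_auprc=area_sum / n,
        n_orderings=n_orderings,
        exhaustive=(mode == "exhaustive"),
    )


def quadrature_segment_area(seg: Segment, n_steps: int = 100_000) -> float:
    """Composite midpoint quadrature of the expectation curve over recall.

    Numeric cross-check for the closed-form continuous segment area; the
    midpoint rule's O(h²) error puts agreement well below 1e-9 at the
    default step counts used in the tests.
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    b, c = seg.d_tp, seg.d_fp
    if b == 0:
        return 0.0
    s = (np.arange(n_steps) + 0.5) * (b / n_steps)
    prec = (b * (seg.tp_a + s)) / (b * (seg.tp_a + s + seg.fp_a) + s * c)
    # ds = b/n_steps, dr = ds/P
    return float(prec.sum() * (b / n_steps) / seg.P)


def mann_whitney_auroc(data: ScoredLabels) -> float:
    """Pairwise AUROC: (#{pos > neg} + ½·#{pos = neg}) / (P·N), exact."""
    pos = data.scores[data.labels == 1]
    neg = data.scores[data.labels == 0]
    if len(pos) == 0:
        raise NoPositivesError("AUROC undefined: no positive entities")
    if len(neg) == 0:
        raise NoNegativesError("AUROC undefined: no negative entities")
    wins = ties = 0
    for p in pos:
        wins += int(np.count_nonzero(p > neg))
        ties += int(np.count_nonzero(p == neg))
    return float(Fraction(2 * wins + ties, 2 * len(pos) * len(neg)))
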