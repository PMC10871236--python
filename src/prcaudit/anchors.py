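"""Input validation, tie grouping, and anchor-point paths.

A binary classifier assigns each entity a real-valued score; thresholding at
``score >= t`` turns scores into predictions. Every *unique* observed score,
used as a threshold, yields one (recall, precision) pair — an anchor point.
Entities sharing a score form a tie group and contribute a single anchor.
Everything downstream (interpolation, AUPRC, AUROC) consumes the cumulative
(tp, fp) path built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    LengthMismatchError,
    NoPositivesError,
    NonBinaryLabelError,
    NonFiniteScoreError,
)

__all__ = [
    "ScoredLabels",
    "TieGroup",
    "AnchorPoint",
    "AnchorPath",
    "validate_scored_labels",
    "group_ties",
    "anchor_path",
    "anchor_path_input_order",
]


@dataclass(frozen=True)
class ScoredLabels:
    """Paired score/label vectors for one classifier on one dataset.

    ``scores`` are finite floats (ties allowed); ``labels`` are 0/1 with
    1 = positive class. Row order is preserved exactly as supplied because
    some emulated tools are sensitive to it.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())


class TieGroup(NamedTuple):
    """A maximal set of entities sharing one score: b positives, c negatives."""

    score: float
    n_pos: int
    n_neg: int

    @property
    def size(self) -> int:
        return self.n_pos + self.n_neg


class AnchorPoint(NamedTuple):
    """Cumulative (tp, fp) at one threshold; precision/recall derived."""

    threshold: float
    tp: int
    fp: int


@dataclass(frozen=True)
class AnchorPath:
    """Ordered anchor points (descending threshold) with class totals.

    Invariants: tp and fp are non-decreasing along the path and the final
    point is (P, N). ``group_sizes[k]`` records how many entities produced
    point k (``> 1`` means a tie block), which selects the tie connector
    during integration.
    """

    points: tuple[AnchorPoint, ...]
    P: int
    N: int
    group_sizes: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.group_sizes:
            object.__setattr__(self, "group_sizes", tuple(1 for _ in self.points))

    def __len__(self) -> int:
        return len(self.points)

    def recall(self, k: int) -> float:
        return self.points[k].tp / self.P

    def precision(self, k: int) -> float:
        p = self.points[k]
        return p.tp / (p.tp + p.fp)


def validate_scored_labels(
    raw_scores: Sequence[float], raw_labels: Sequence[int]
) -> ScoredLabels:
    """Validate raw input and return a :class:`ScoredLabels`.

    Raises
    ------
    LengthMismatchError, EmptyInputError, NonBinaryLabelError,
    NonFiniteScoreError
        Each condition gets its own exception type so callers can react to
        the precise defect.
    """
    scores = np.asarray(raw_scores, dtype=float)
    try:
        labels = np.asarray(raw_labels)
    except (TypeError, ValueError) as exc:  # pragma: no cover - numpy coerces most
        raise NonBinaryLabelError(f"labels not interpretable as 0/1: {exc}") from exc
    if scores.ndim != 1 or labels.ndim != 1:
        raise LengthMismatchError("scores and labels must be one-dimensional")
    if len(scores) != len(labels):
        raise LengthMismatchError(
            f"length mismatch: {len(scores)} scores vs {len(labels)} labels"
        )
    if len(scores) == 0:
        raise EmptyInputError("empty input: need at least one entity")
    if not np.all(np.isfinite(scores)):
        bad = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise NonFiniteScoreError(f"non-finite score at row {bad}: {scores[bad]}")
    if labels.dtype.kind not in "biu" and not np.all(labels == labels.astype(int)):
        raise NonBinaryLabelError("non-binary label: labels must be integers 0 or 1")
    labels = labels.astype(np.int64)
    if not np.all((labels == 0) | (labels == 1)):
        bad = int(np.flatnonzero((labels != 0) & (labels != 1))[0])
        raise NonBinaryLabelError(f"non-binary label at row {bad}: {labels[bad]}")
    return ScoredLabels(scores=scores, labels=labels)



def group_ties(data: ScoredLabels) -> list[TieGroup]:
    """Group entities by exact score equality, sorted by descending score.

    Exact floating equality is deliberate: a tie means *the same* score, and
    an epsilon tolerance would silently merge distinct thresholds. Callers
    who want coarser ties can round scores first.
    """
    order = np.argsort(-data.scores, kind="stable")
    s = data.scores[order]
    y = data.labels[order]
    # boundaries where the (descending) score changes
    boundaries = np.flatnonzero(np.diff(s) != 0) + 1
    groups: list[TieGroup] = []
    start = 0
    for end in [*boundaries.tolist(), len(s)]:
        block = y[start:end]
        groups.append(
            TieGroup(score=float(s[start]), n_pos=int(block.sum()), n_neg=int(len(block) - block.sum()))
        )
        start = end
    return groups


def anchor_path(groups: Sequence[TieGroup]) -> AnchorPath:
    """Build the cumulative (tp, fp) anchor path from tie groups.

    Point k accumulates the positives/negatives of groups 0..k; the final
    point is therefore (P, N).
    """
    if len(groups) == 0:
        raise EmptyInputError("no tie groups supplied")
    P = sum(g.n_pos for g in groups)
    N = sum(g.n_neg for g in groups)
    if P == 0:
        raise NoPositivesError("AUPRC undefined: no positive entities")
    tp = fp = 0
    points = []
    sizes = []
    for g in groups:
        tp += g.n_pos
        fp += g.n_neg
        points.append(AnchorPoint(threshold=g.score, tp=tp, fp=fp))
        sizes.append(g.size)
    return AnchorPath(points=tuple(points), P=P, N=N, group_sizes=tuple(sizes))


def anchor_path_input_order(data: ScoredLabels) -> AnchorPath:
    """Per-entity anchor path that breaks ties by input order.

    Emulates tools that stable-sort by descending score and then treat every
    entity as a distinct threshold, so the path has one point per entity and
    depends on row order whenever ties exist. Tie-free data gives the same
    path as :func:`anchor_path`.
    """
    if data.n_pos == 0:
        raise NoPositivesError("AUPRC undefined: no positive entities")
    order = np.argsort(-data.scores, kind="stable")
    tp = fp = 0
    points = []
    for i in order:
        if data.labels[i] == 1:
            tp += 1
        else:
            fp += 1
        points.append(AnchorPoint(threshold=float(data.scores[i]), tp=tp, fp=fp))
    return AnchorPath(
        points=tuple(points),
        P=data.n_pos,
        N=data.n_neg,
        group_sizes=tuple(1 for _ in points),
    )
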