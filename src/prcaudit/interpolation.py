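"""Segment connectors between adjacent anchor points.

Between two anchors A = (tp_A, fp_A) and B = (tp_B, fp_B) the PR curve is
not observed; four conventions fill the gap:

* **line / linear** — a straight chord in (recall, precision) space;
  the area is a trapezoid.
* **discrete expectation** — interpolated points at the *expected*
  coordinates of intermediate true-positive counts, joined by chords.
* **continuous expectation** — the same expectation as a continuous curve,
  integrated in closed form.
* **step** — a step curve at the precision of B; the area is a rectangle
  (this is the Average Precision convention).

The expectation treats the ΔTP = tp_B − tp_A positives and
ΔFP = fp_B − fp_A negatives of the tie block as arriving in random order,
with false positives accruing linearly in true positives: after s of the
block's positives, fp_A + s·ΔFP/ΔTP false positives are expected, giving

    precision(s) = (tp_A + s) / (tp_A + s + fp_A + s·ΔFP/ΔTP),  0 ≤ s ≤ ΔTP.

Whenever precision decreases across the block this curve is convex in
(recall, precision), so the straight chord (linear interpolation) lies above
it and over-estimates the area — the core inflation mechanism this package
diagnoses. (Where precision rises the curve is concave and the ordering
reverses.)

Areas that only involve rational quantities (trapezoids, rectangles,
discrete-expectation chords, and the constant-precision special case of the
continuous form) are computed in exact rational arithmetic so that
downstream equalities (e.g. constant classifier ⇒ AUPRC = P/(P+N)) are
bit-exact; only the logarithmic closed form uses floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Union

from .errors import VerticalSegmentError

__all__ = [
    "Segment",
    "CurveVertex",
    "expectation_precision",
    "discrete_expectation_vertices",
    "continuous_segment_area",
    "linear_segment_area",
    "step_segment_area",
]

Number = Union[int, float, Fraction]


@dataclass(frozen=True)
class Segment:
    """One inter-anchor interval: counts at both ends plus the positive total P."""

    tp_a: int
    fp_a: int
    tp_b: int
    fp_b: int
    P: int

    def __post_init__(self) -> None:
        if self.tp_b < self.tp_a or self.fp_b < self.fp_a:
            raise ValueError("segment counts must be non-decreasing")
        if self.tp_b == self.tp_a and self.fp_b == self.fp_a:
            raise ValueError("degenerate segment: both deltas zero")
        if self.P < 1:
            raise ValueError("P must be >= 1")

    @property
    def d_tp(self) -> int:
        return self.tp_b - self.tp_a

    @property
    def d_fp(self) -> int:
        return self.fp_b - self.fp_a

    @property
    def recall_a(self) -> Fraction:
        return Fraction(self.tp_a, self.P)

    @property
    def recall_b(self) -> Fraction:
        return Fraction(self.tp_b, self.P)

    def precision_a(self) -> Fraction:
        if self.tp_a + self.fp_a == 0:
            raise ValueError("precision undefined at tp + fp = 0")
        return Fraction(self.tp_a, self.tp_a + self.fp_a)

    def precision_b(self) -> Fraction:
        return Fraction(self.tp_b, self.tp_b + self.fp_b)

    def start_limit_precision(self) -> Fraction:
        """Precision limit of the expectation/step curve as tp → 0⁺.

        On the origin segment (tp_a = fp_a = 0) the expectation curve is
        constant at ΔTP/(ΔTP+ΔFP); elsewhere it is simply the precision at A.
        """
        if self.tp_a + self.fp_a > 0:
            return self.precision_a()
        if self.d_tp == 0:
            return Fraction(0)
        return Fraction(self.d_tp, self.d_tp + self.d_fp)


@dataclass(frozen=True)
class CurveVertex:
    """A point on an emitted PR curve."""

    recall: float
    precision: float
    kind: Literal["anchor", "interpolated", "start", "end"]


def expectation_precision(seg: Segment, s: Number) -> Number:
    """Expected precision after s of the segment's ΔTP positives (0 ≤ s ≤ ΔTP).

    Returns a Fraction when ``s`` is int/Fraction (exact), a float otherwise.
    """
    b, c = seg.d_tp, seg.d_fp
    if b == 0:
        raise VerticalSegmentError("expectation undefined on vertical segment")
    if s < 0 or s > b:
        raise ValueError(f"s={s} outside [0, {b}]")
    if isinstance(s, float) and not s.is_integer():
        num = b * (seg.tp_a + s)
        return num / (b * (seg.tp_a + s + seg.fp_a) + s * c)
    s = Fraction(s)
    # cleared of the c/b ratio: all-integer numerator/denominator
    return Fraction(b * (seg.tp_a + s), b * (seg.tp_a + s + seg.fp_a) + s * c)


def discrete_expectation_vertices(
    seg: Segment, offset: float = 1.0
) -> list[CurveVertex]:
    """Interpolated vertices on the expectation curve at s = offset, offset+1, … < ΔTP.

    ``offset=0.5`` is the convention for connecting distinct-score anchors
    (the interpolated point sits mid-way through the single new positive);
    ``offset=1.0`` places a point at every whole intermediate true-positive
    count of a tie block. Adjacent vertices are later joined by chords.
    """
    b = seg.d_tp
    if b == 0:
        raise VerticalSegmentError("expectation undefined on vertical segment")
    off = Fraction(offset).limit_denominator(10**6)
    vertices = []
    s = off
    while s < b:
        prec = expectation_precision(seg, s)
        rec = Fraction(seg.tp_a + s, seg.P)
        vertices.append(
            CurveVertex(recall=float(rec), precision=float(prec), kind="interpolated")
        )
        s += 1
    return vertices


def _discrete_expectation_interior(seg: Segment, offset: Fraction):
    """Exact (recall, precision) Fractions of the interior vertices."""
    pts = []
    s = offset
    while s < seg.d_tp:
        pts.append((Fraction(seg.tp_a + s, seg.P), expectation_precision(seg, s)))
        s += 1
    return pts


def discrete_expectation_segment_area(
    seg: Segment,
    offset: float = 1.0,
    start_precision: Number | None = None,
) -> Fraction:
    """Area under the chord polyline A → interpolated vertices → B.

    ``start_precision`` overrides the precision of the segment's left end —
    used for the virtual origin segment, whose anchor-A precision is a limit
    (or a forced (0,1) start when emulating that issue).
    """
    if seg.d_tp == 0:
        return Fraction(0)
    off = Fraction(offset).limit_denominator(10**6)
    p_a = Fraction(start_precision) if start_precision is not None else (
        seg.start_limit_precision() if seg.tp_a + seg.fp_a == 0 else seg.precision_a()
    )
    pts = [(seg.recall_a, p_a)]
    pts += _discrete_expectation_interior(seg, off)
    pts.append((seg.recall_b, seg.precision_b()))
    area = Fraction(0)
    for (r0, q0), (r1, q1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (q0 + q1) / 2
    return area


def continuous_segment_area(seg: Segment) -> Number:
    """∫ precision d(recall) with precision on the continuous expectation curve.

    With β = 1 + ΔFP/ΔTP and C = tp_A + fp_A the closed form is

        area = (1/P) · [ ΔTP/β + (tp_A − C/β) · (1/β) · ln((C + β·ΔTP)/C) ].

    When tp_A·ΔFP = fp_A·ΔTP (which covers the origin block C = 0) the
    integrand is the constant ΔTP/(ΔTP+ΔFP) and the exact rational area is
    returned. Vertical segments (ΔTP = 0) contribute zero.
    """
    b, c = seg.d_tp, seg.d_fp
    if b == 0:
        return Fraction(0)
    if seg.tp_a * c == seg.fp_a * b:
        # constant precision b/(b+c) across the whole segment
        return Fraction(b, b + c) * Fraction(b, seg.P)
    beta = 1.0 + c / b
    C = seg.tp_a + seg.fp_a
    coef = seg.tp_a - C / beta
    area = b / beta
    if coef != 0.0 and C > 0:
        area += coef / beta * math.log((C + beta * b) / C)
    return area / seg.P


def linear_segment_area(
    seg: Segment, start_precision: Number | None = None
) -> Fraction:
    """Trapezoid between the two anchors: (R_B − R_A)·(prec_A + prec_B)/2.

    ``start_precision`` supplies the left-end precision for the origin
    segment, where anchor A has no defined precision of its own.
    """
    if seg.d_tp == 0:
        return Fraction(0)
    if start_precision is not None:
        p_a = Fraction(start_precision)
    elif seg.tp_a + seg.fp_a == 0:
        # straight-line convention: start at the first anchor's precision
        p_a = seg.precision_b()
    else:
        p_a = seg.precision_a()
    return (seg.recall_b - seg.recall_a) * (p_a + seg.precision_b()) / 2


def step_segment_area(seg: Segment) -> Fraction:
    """Rectangle at the precision of B: (R_B − R_A)·prec_B (the AP convention)."""
    if seg.d_tp == 0:
        return Fraction(0)
    return (seg.recall_b - seg.recall_a) * seg.precision_b()
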