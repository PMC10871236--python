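"""Full PR curves and AUPRC/AP/AUROC estimators under a method recipe.

A :class:`MethodSpec` pins down everything a tool implicitly chooses when it
computes AUPRC: how distinct-score anchors are connected, how tie-block
anchors are connected, where the curve starts at recall 0, whether the curve
covers recall up to 1, and whether ties are grouped or broken by input
order. Different published tools make different combinations of these
choices, which is why they disagree on the same data; the presets live in
:mod:`prcaudit.profiles`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from typing import Literal

import pandas as pd

from .anchors import (
    AnchorPath,
    ScoredLabels,
    anchor_path,
    anchor_path_input_order,
    group_ties,
)
from .errors import NoNegativesError, NoPositivesError
from .interpolation import (
    CurveVertex,
    Segment,
    continuous_segment_area,
    discrete_expectation_segment_area,
    discrete_expectation_vertices,
    expectation_precision,
    linear_segment_area,
    step_segment_area,
)

__all__ = [
    "MethodSpec",
    "AUPRCResult",
    "PRCurve",
    "DEFAULT_SPEC",
    "AP_SPEC",
    "prc_curve",
    "auprc",
    "average_precision",
    "baseline_auprc",
    "auroc",
]

NoTiesConnector = Literal["line", "discrete_expectation", "continuous_expectation", "step"]
TiesConnector = Literal["linear", "discrete_expectation", "continuous_expectation", "step"]
StartPolicy = Literal["segment_limit", "fixed_0_1", "first_anchor"]
EndPolicy = Literal["full_recall", "truncate_at_last_distinct"]
TiePolicy = Literal["group", "input_order"]

_NO_TIES = {"line", "discrete_expectation", "continuous_expectation", "step"}
_TIES = {"linear", "discrete_expectation", "continuous_expectation", "step"}
_STARTS = {"segment_limit", "fixed_0_1", "first_anchor"}
_ENDS = {"full_recall", "truncate_at_last_distinct"}
_TIE_POLICIES = {"group", "input_order"}

# interpolated-sample density for rendering the continuous expectation curve
_CONTINUOUS_SAMPLES = 12


@dataclass(frozen=True)
class MethodSpec:
    """A complete AUPRC recipe: connectors, start/end policy, tie policy."""

    no_ties_connector: NoTiesConnector = "line"
    ties_connector: TiesConnector = "continuous_expectation"
    start_policy: StartPolicy = "segment_limit"
    end_policy: EndPolicy = "full_recall"
    tie_policy: TiePolicy = "group"

    def __post_init__(self) -> None:
        if self.no_ties_connector not in _NO_TIES:
            raise ValueError(f"unknown no-ties connector: {self.no_ties_connector}")
        if self.ties_connector not in _TIES:
            raise ValueError(f"unknown ties connector: {self.ties_connector}")
        if self.start_policy not in _STARTS:
            raise ValueError(f"unknown start policy: {self.start_policy}")
        if self.end_policy not in _ENDS:
            raise ValueError(f"unknown end policy: {self.end_policy}")
        if self.tie_policy not in _TIE_POLICIES:
            raise ValueError(f"unknown tie policy: {self.tie_policy}")


#: The issue-free default: straight lines between distinct anchors,
#: continuous expectation across tie blocks, complete curve.
DEFAULT_SPEC = MethodSpec()

#: Average Precision: step curves everywhere.
AP_SPEC = MethodSpec(no_ties_connector="step", ties_connector="step")


@dataclass(frozen=True)
class AUPRCResult:
    """An AUPRC value together with the recipe and any issue warnings raised."""

    value: float
    method: MethodSpec
    warnings: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {"value": self.value, "method": asdict(self.method), "warnings": list(self.warnings)}
        )


@dataclass(frozen=True)
class PRCurve:
    """An emitted PR curve: ordered vertices plus per-interval connector kinds."""

    vertices: tuple[CurveVertex, ...]
    segment_kinds: tuple[str, ...]
    method: MethodSpec
    warnings: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recall": [v.recall for v in self.vertices],
                "precision": [v.precision for v in self.vertices],
                "kind": [v.kind for v in self.vertices],
            }
        )


def _build_path(data: ScoredLabels, spec: MethodSpec) -> AnchorPath:
    if spec.tie_policy == "input_order":
        return anchor_path_input_order(data)
    return anchor_path(group_ties(data))


def _segments(path: AnchorPath) -> list[tuple[Segment, bool, bool]]:
    """(segment, is_tie_block, is_origin) triples, origin segment included."""
    out = []
    prev_tp = prev_fp = 0
    for k, pt in enumerate(path.points):
        seg = Segment(tp_a=prev_tp, fp_a=prev_fp, tp_b=pt.tp, fp_b=pt.fp, P=path.P)
        out.append((seg, path.group_sizes[k] > 1, k == 0))
        prev_tp, prev_fp = pt.tp, pt.fp
    return out


def _connector_for(spec: MethodSpec, is_tie: bool) -> str:
    name = spec.ties_connector if is_tie else spec.no_ties_connector
    return "line" if name == "linear" else name


def _segment_area(
    seg: Segment, connector: str, is_tie: bool, is_origin: bool, spec: MethodSpec
):
    """Area contribution of one segment under the chosen connector.

    The origin segment is virtual: its left end has no defined precision, so
    the start policy decides the chord anchor for polyline connectors
    (straight line / discrete expectation). ``first_anchor`` omits the origin
    segment altogether; ``fixed_0_1`` pins the chord start at precision 1;
    the forced (0,1) point never alters rectangle or closed-form areas.
    """
    if is_origin and spec.start_policy == "first_anchor":
        return Fraction(0)
    start_prec = None
    if is_origin and spec.start_policy == "fixed_0_1":
        start_prec = 1
    if connector == "line":
        return linear_segment_area(seg, start_precision=start_prec)
    if connector == "step":
        return step_segment_area(seg)
    if connector == "continuous_expectation":
        return continuous_segment_area(seg)
    if connector == "discrete_expectation":
        offset = 1.0 if is_tie else 0.5
        return discrete_expectation_segment_area(seg, offset=offset, start_precision=start_prec)
    raise AssertionError(connector)


def _collect_warnings(path: AnchorPath, spec: MethodSpec) -> list[str]:
    w = []
    has_ties = any(s > 1 for s in path.group_sizes)
    if spec.tie_policy == "group" and has_ties and spec.ties_connector == "linear":
        w.append("ties present + linear interpolation: AUPRC may be overly optimistic")
    if spec.start_policy == "fixed_0_1":
        w.append("start point forced to (0, 1)")
    if spec.start_policy == "first_anchor":
        w.append("curve starts at the first anchor; recall range [0, r1) not covered")
    if spec.tie_policy == "input_order" and has_ties:
        w.append("tie order taken from input row order: result depends on row order")
    if path.N == 0:
        w.append("no negative entities: precision identically 1, AUPRC = 1")
    return w


def prc_curve(data: ScoredLabels, spec: MethodSpec = DEFAULT_SPEC) -> PRCurve:
    """Assemble the full PR curve (vertices + connector kinds) for one recipe.

    The curve always contains every anchor point. Under
    ``start_policy='segment_limit'`` the recall-0 vertex takes the precision
    limit of the first segment's connector as tp → 0, which for every
    connector equals the first anchor's precision; ``fixed_0_1`` forces
    (0, 1); ``first_anchor`` emits no recall-0 vertex at all.
    """
    path = _build_path(data, spec)
    warnings = _collect_warnings(path, spec)
    segs = _segments(path)
    vertices: list[CurveVertex] = []
    kinds: list[str] = []

    first_seg = segs[0][0]
    if spec.start_policy == "fixed_0_1":
        vertices.append(CurveVertex(0.0, 1.0, "start"))
    elif spec.start_policy == "segment_limit":
        vertices.append(CurveVertex(0.0, float(first_seg.start_limit_precision()), "start"))

    for seg, is_tie, is_origin in segs:
        connector = _connector_for(spec, is_tie)
        if is_origin and spec.start_policy == "first_anchor":
            pass  # no interior: curve begins at anchor B of this segment
        elif seg.d_tp == 0:
            pass  # vertical drop: drawn implicitly by the next anchor vertex
        elif connector == "step":
            vertices.append(
                CurveVertex(float(seg.recall_a), float(seg.precision_b()), "interpolated")
            )
        elif connector == "discrete_expectation":
            vertices.extend(discrete_expectation_vertices(seg, offset=1.0 if is_tie else 0.5))
        elif connector == "continuous_expectation":
            for j in range(1, _CONTINUOUS_SAMPLES):
                s = seg.d_tp * j / _CONTINUOUS_SAMPLES
                vertices.append(
                    CurveVertex(
                        (seg.tp_a + s) / seg.P,
                        float(expectation_precision(seg, s)),
                        "interpolated",
                    )
                )
        vertices.append(
            CurveVertex(float(seg.recall_b), float(seg.precision_b()), "anchor")
        )
        kinds.append(connector)

    if spec.end_policy == "truncate_at_last_distinct":
        for i, v in enumerate(vertices):
            if v.kind == "anchor" and v.recall == 1.0:
                if i + 1 < len(vertices):
                    vertices = vertices[: i + 1]
                    warnings = warnings + ["curve truncated after first full-recall anchor"]
                break

    return PRCurve(
        vertices=tuple(vertices),
        segment_kinds=tuple(kinds),
        method=spec,
        warnings=tuple(warnings),
    )


def auprc(data: ScoredLabels, spec: MethodSpec = DEFAULT_SPEC) -> AUPRCResult:
    """AUPRC under a full method recipe.

    Each inter-anchor segment is integrated with the connector selected by
    whether its tie group holds more than one entity (mixed dispatch, the way
    real tools combine their no-ties and ties methods); the virtual origin
    segment is handled by the start policy.
    """
    path = _build_path(data, spec)
    total = Fraction(0)
    for seg, is_tie, is_origin in _segments(path):
        total = total + _segment_area(seg, _connector_for(spec, is_tie), is_tie, is_origin, spec)
    return AUPRCResult(
        value=float(total), method=spec, warnings=tuple(_collect_warnings(path, spec))
    )


def average_precision(data: ScoredLabels) -> float:
    """Average Precision: the step-curve AUPRC, Σ (R_k − R_{k−1})·prec_k."""
    return auprc(data, AP_SPEC).value


def baseline_auprc(P: int, N: int) -> float:
    """Expected AUPRC of an uninformative classifier: the prevalence P/(P+N)."""
    if P < 1:
        raise NoPositivesError("AUPRC undefined: no positive entities")
    if N < 0:
        raise ValueError("negative count N")
    return float(Fraction(P, P + N))


def auroc(data: ScoredLabels) -> float:
    """Trapezoid area under the ROC curve built from grouped tie anchors.

    Computed in exact rational arithmetic; equals the pairwise
    probability statistic P(score_pos > score_neg) + ½·P(tie).
    """
    path = anchor_path(group_ties(data))
    if path.N == 0:
        raise NoNegativesError("AUROC undefined: no negative entities")
    acc = 0  # 2·P·N times the area, an integer
    prev_tp = prev_fp = 0
    for pt in path.points:
        acc += (pt.fp - prev_fp) * (pt.tp + prev_tp)
        prev_tp, prev_fp = pt.tp, pt.fp
    return float(Fraction(acc, 2 * path.P * path.N))
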