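import math

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from prcaudit import (
    AP_SPEC,
    MethodSpec,
    auprc,
    auroc,
    average_precision,
    baseline_auprc,
    make_tie_block_fixture,
    prc_curve,
    validate_scored_labels,
)
from prcaudit.errors import NoNegativesError, NoPositivesError
from tests.helpers import random_dataset

LINEAR_SPEC = MethodSpec(ties_connector="linear")
CONT_SPEC = MethodSpec(
    no_ties_connector="continuous_expectation", ties_connector="continuous_expectation"
)


class TestPRCurve:
    def test_straight_line_curve_vertices(self, d1):
        crv = prc_curve(d1, LINEAR_SPEC)
        got = [(v.recall, v.precision) for v in crv.vertices]
        expected = [(0, 1), (1 / 3, 1), (2 / 3, 1), (2 / 3, 2 / 3), (1, 3 / 4), (1, 3 / 5)]
        assert got == pytest.approx(expected)
        assert crv.vertices[0].kind == "start"
        assert all(
            a.recall <= b.recall for a, b in zip(crv.vertices, crv.vertices[1:])
        ), "recall must be non-decreasing along the curve"

    def test_constant_classifier_continuous_curve_is_horizontal(self, constant_3_2):
        crv = prc_curve(constant_3_2, CONT_SPEC)
        assert crv.vertices[0].recall == 0 and crv.vertices[0].precision == pytest.approx(0.6)
        assert crv.vertices[-1].recall == 1 and crv.vertices[-1].precision == pytest.approx(0.6)
        assert all(v.precision == pytest.approx(0.6) for v in crv.vertices)

    def test_constant_classifier_forced_start_is_a_single_chord(self, constant_3_2):
        spec = MethodSpec(ties_connector="linear", start_policy="fixed_0_1")
        crv = prc_curve(constant_3_2, spec)
        assert [(v.recall, v.precision) for v in crv.vertices] == pytest.approx(
            [(0, 1), (1, 0.6)]
        )

    def test_all_anchors_present_even_at_vertical_drops(self, d1):
        crv = prc_curve(d1, AP_SPEC)
        anchors = {(v.recall, v.precision) for v in crv.vertices if v.kind == "anchor"}
        assert (2 / 3, 2 / 3) in anchors and (1.0, 0.6) in anchors

    def test_truncation_stops_curve_at_first_full_recall_anchor(self):
        data = make_tie_block_fixture([(1, 0), (1, 0), (0, 1)])
        spec = MethodSpec(end_policy="truncate_at_last_distinct")
        crv = prc_curve(data, spec)
        assert crv.vertices[-1].recall == 1.0 and crv.vertices[-1].precision == 1.0
        assert "curve truncated after first full-recall anchor" in crv.warnings

    def test_first_anchor_start_omits_recall_zero_vertex(self, d1):
        crv = prc_curve(d1, MethodSpec(start_policy="first_anchor"))
        assert crv.vertices[0].recall == pytest.approx(1 / 3)


class TestAUPRC:
    def test_worked_example_under_three_recipes(self, d1):
        assert auprc(d1, LINEAR_SPEC).value == pytest.approx(65 / 72)
        assert auprc(d1, AP_SPEC).value == pytest.approx(11 / 12)
        assert auprc(d1, CONT_SPEC).value == pytest.approx(
            2 / 3 + (1 - math.log(4 / 3)) / 3
        )

    def test_constant_classifier_values(self, constant_3_2):
        assert auprc(constant_3_2, CONT_SPEC).value == 0.6
        assert average_precision(constant_3_2) == 0.6
        inflated = auprc(
            constant_3_2, MethodSpec(ties_connector="linear", start_policy="fixed_0_1")
        )
        assert inflated.value == 0.8

    def test_ties_connector_irrelevant_without_ties(self, d1):
        values = {
            auprc(d1, MethodSpec(ties_connector=tc)).value
            for tc in ["linear", "discrete_expectation", "continuous_expectation", "step"]
        }
        assert len(values) == 1

    def test_warning_raised_for_linear_interpolation_of_ties(self, constant_3_2):
        res = auprc(constant_3_2, LINEAR_SPEC)
        assert any("linear interpolation" in w for w in res.warnings)
        assert not any("linear" in w for w in auprc(constant_3_2, CONT_SPEC).warnings)

    def test_zero_positives_error(self):
        with pytest.raises(NoPositivesError):
            auprc(validate_scored_labels([0.4, 0.2], [0, 0]))

    def test_zero_negatives_allowed_with_warning(self):
        res = auprc(validate_scored_labels([0.4, 0.2], [1, 1]))
        assert res.value == 1.0
        assert any("no negative entities" in w for w in res.warnings)

    def test_result_json_round_trip(self, d1):
        import json

        payload = json.loads(auprc(d1).to_json())
        assert payload["value"] == auprc(d1).value
        assert payload["method"]["ties_connector"] == "continuous_expectation"

    def test_ap_monotone_in_tie_free_positive_promotion(self):
        """Raising one positive's score never decreases AP on tie-free data.

        A promotion past positives is a no-op for the ranking; past
        negatives it strictly improves every affected precision step.
        """
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 60:
            data = random_dataset(rng, max_n=12, force_ties=False)
            pos_rows = np.flatnonzero(data.labels == 1)
            row = int(rng.choice(pos_rows))
            raised = data.scores.copy()
            raised[row] += float(rng.random() + 0.05)
            if len(set(raised.tolist())) < len(raised):
                continue  # promotion landed on an existing score: no longer tie-free
            before = average_precision(data)
            after = average_precision(validate_scored_labels(raised, data.labels))
            assert after >= before - 1e-12
            checked += 1

    def test_ap_can_decrease_when_a_promotion_splits_a_tie_block(self):
        """Grouped-tie AP is *not* monotone under arbitrary score raises.

        Splitting a tied positive block (without crossing the negative
        above it) replaces one rectangle at the block's end precision with
        smaller intermediate steps: 5/6 drops to 29/36. scikit-learn's
        average_precision_score shows the same decrease.
        """
        before = validate_scored_labels([0.2, 0.7, 0.2, 0.4], [1, 1, 1, 0])
        after = validate_scored_labels([0.25, 0.7, 0.2, 0.4], [1, 1, 1, 0])
        assert average_precision(before) == pytest.approx(5 / 6)
        assert average_precision(after) == pytest.approx(29 / 36)
        assert average_precision_score(before.labels, before.scores) == pytest.approx(5 / 6)
        assert average_precision_score(after.labels, after.scores) == pytest.approx(29 / 36)


class TestLimits:
    @pytest.mark.parametrize(
        "spec",
        [
            LINEAR_SPEC,
            AP_SPEC,
            CONT_SPEC,
            MethodSpec(no_ties_connector="discrete_expectation", ties_connector="discrete_expectation"),
        ],
        ids=["line", "step", "continuous", "discrete"],
    )
    def test_perfect_separation_gives_unit_area(self, spec):
        data = validate_scored_labels([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        assert auprc(data, spec).value == 1.0

    def test_constant_scores_give_exact_prevalence_under_expectation_and_ap(self):
        for P, N in [(3, 2), (1, 3), (7, 13)]:
            data = make_tie_block_fixture([(P, N)])
            for spec in (CONT_SPEC, AP_SPEC, MethodSpec(ties_connector="discrete_expectation")):
                assert auprc(data, spec).value == P / (P + N)


class TestAUROC:
    def test_worked_example(self, d1):
        assert auroc(d1) == 5 / 6

    def test_constant_scores_give_half(self, constant_3_2):
        assert auroc(constant_3_2) == 0.5

    def test_perfect_and_reversed_classifiers(self):
        assert auroc(validate_scored_labels([3.0, 2.0, 1.0], [1, 1, 0])) == 1.0
        assert auroc(validate_scored_labels([3.0, 2.0, 1.0], [0, 0, 1])) == 0.0

    def test_single_class_errors(self):
        with pytest.raises(NoNegativesError):
            auroc(validate_scored_labels([0.4, 0.2], [1, 1]))
        with pytest.raises(NoPositivesError):
            auroc(validate_scored_labels([0.4, 0.2], [0, 0]))

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            data = random_dataset(rng, force_ties=bool(rng.integers(2)))
            transformed = validate_scored_labels(
                np.exp(3.0 * data.scores) - 1.0, data.labels
            )
            assert auroc(data) == auroc(transformed)


class TestCrossChecksAgainstSklearn:
    """Dual-route checks: our Fraction-based estimators vs scikit-learn."""

    def test_average_precision_matches(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            data = random_dataset(rng, force_ties=bool(rng.integers(2)))
            expected = average_precision_score(data.labels, data.scores)
            assert average_precision(data) == pytest.approx(expected, abs=1e-12)

    def test_auroc_matches(self):
        rng = np.random.default_rng(4)
        for _ in range(150):
            data = random_dataset(rng, force_ties=bool(rng.integers(2)))
            expected = roc_auc_score(data.labels, data.scores)
            assert auroc(data) == pytest.approx(expected, abs=1e-12)


class TestBaseline:
    def test_prevalence(self):
        assert baseline_auprc(1, 1) == 0.5
        assert baseline_auprc(3, 0) == 1.0

    def test_zero_positives_rejected(self):
        with pytest.raises(NoPositivesError):
            baseline_auprc(0, 5)


def test_global_ordering_on_decreasing_precision_curves():
    """AP <= continuous expectation <= linear when precision only falls.

    Built from tie-block fixtures whose anchor precisions are non-increasing,
    so every segment is a falling one and the segment-level ordering sums.
    """
    specs = [
        [(2, 0), (3, 2)],
        [(1, 0), (2, 1), (1, 3)],
        [(3, 1), (2, 2), (1, 4)],
    ]
    for blocks in specs:
        data = make_tie_block_fixture(blocks)
        ap = auprc(data, AP_SPEC).value
        cont = auprc(data, MethodSpec()).value
        lin = auprc(data, LINEAR_SPEC).value
        assert ap <= cont + 1e-12 <= lin + 2e-12
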