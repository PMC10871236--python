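# Methods

## Anchor points and the classification rule

Entities are classified positive when `score ≥ t`. Every unique observed
score, taken as `t`, gives cumulative counts (tp, fp) and hence one anchor
point (recall, precision) = (tp/P, tp/(tp+fp)). Entities sharing a score
form a tie group and define a single anchor; grouping uses **exact**
floating-point equality, with no epsilon — a tie means the same score, and a
tolerance would silently merge distinct thresholds (callers who want coarser
ties can round their scores first). The anchor path therefore ends at
(P, N), so the final anchor always has recall 1.

Degenerate inputs: a dataset with no positives has no defined AUPRC and
raises; a dataset with no negatives is allowed (precision is identically 1,
AUPRC is 1) and carries a warning. Validation failures each raise a distinct
exception type (length mismatch, empty input, non-binary label, non-finite
score).

## The expectation model for tie blocks

Within a segment from anchor A = (tp_A, fp_A) to B = (tp_B, fp_B)
(ΔTP = b new positives, ΔFP = c new negatives), the expectation connector
models the tied entities as arriving in random order with false positives
accruing **linearly in true positives**: after s positives, fp_A + s·c/b
false positives, giving

    precision(s) = (tp_A + s) / (tp_A + s + fp_A + s·c/b),  0 ≤ s ≤ b.

This linear-fp form is adopted because it passes through both anchors,
reproduces the prevalence P/(P+N) exactly for a constant (single-block)
classifier, and matches the behaviour of the tools that use expectation
interpolation. A genuinely combinatorial alternative exists — the expected
false-positive count over uniformly random orderings is
E[fp | tp = s] = s·c/(b+1), not s·c/b — and the oracle module computes it by
enumeration so the interior gap between the two conventions can be
inspected; the estimators use the linear-fp form throughout.

Where precision falls across the segment this curve is convex in
(recall, precision); where it rises, concave. Hence the per-segment area
ordering: step ≤ continuous expectation ≤ straight chord on falling
segments, reversed on rising ones, equality when flat. Falling mixed tie
blocks are the common case for real discrete-score classifiers, which is
exactly why linear tie interpolation is systematically optimistic.

## Connectors and their areas

- straight line: trapezoid (R_B − R_A)(prec_A + prec_B)/2.
- discrete expectation: chords through interpolated vertices at s = 0.5
  (distinct-score segments, one midpoint) or s = 1, 2, …, b−1 (tie blocks);
  the vertices lie exactly on the continuous expectation curve.
- continuous expectation: closed form with β = 1 + c/b, C = tp_A + fp_A:
  area = (1/P)[b/β + (tp_A − C/β)(1/β)·ln((C + βb)/C)], the log term
  dropped when its coefficient vanishes (tp_A·c = fp_A·b, which includes
  the origin block C = 0, where the integrand is the constant b/(b+c)).
- step (AP): rectangle (R_B − R_A)·prec_B.

Vertical segments (ΔTP = 0, a pure precision drop at fixed recall)
contribute zero area under every connector but are always emitted as curve
vertices, so no anchor is ever missing from an exported curve.

A full recipe (`MethodSpec`) additionally fixes:

- **dispatch** — a segment produced by a multi-entity tie group uses the
  ties connector; unit segments use the no-ties connector (this is how real
  tools combine their two documented methods);
- **start policy** — the curve's recall-0 vertex. `segment_limit` (default)
  uses the first segment connector's precision limit as tp → 0⁺, which for
  every connector equals the first anchor's precision; `fixed_0_1` forces
  (0, 1); `first_anchor` emits no recall-0 vertex and omits the origin
  segment's area. The forced (0, 1) start changes the integral only through
  chord-based connectors (straight line, discrete expectation) on the
  origin segment; rectangle and closed-form areas never consult the start
  vertex, so for step/continuous recipes the forced start is a plotted
  point only. Anchor precision at tp + fp = 0 is never evaluated anywhere.
- **end policy** — `full_recall` keeps the whole path (the last anchor has
  recall 1 by construction); `truncate_at_last_distinct` stops the emitted
  curve at the first anchor reaching recall 1, dropping any trailing
  vertical tail of pure false positives. The truncation changes the curve,
  not the area (the dropped segments are vertical); the area effect of an
  incomplete recall range is carried by the `first_anchor` start policy.
- **tie policy** — `group` (one anchor per unique score) or `input_order`
  (stable sort by descending score, one anchor per entity), the latter only
  for emulating tools whose results depend on row order.

## Exact arithmetic

All chord, rectangle, and discrete-expectation areas — and the trapezoid
AUROC — are computed in `fractions.Fraction`: the inputs are integer counts
and half-integer offsets, so these areas are rational and exact. The
continuous closed form uses floats only when the logarithm actually
appears. Consequences the test suite relies on: trapezoid AUROC equals the
pairwise Mann–Whitney statistic bit-for-bit (both are the same correctly
rounded rational), a constant classifier yields exactly P/(P+N) under
expectation and AP recipes, and the linear-from-(0,1) recipe yields exactly
(1 + P/(P+N))/2.

## Tool profiles and the audit

The 13 presets encode the documented connector pairs, start/end policies,
tie policies, and issue flags of the common tools (one preset per method
for tools offering several). Tool-specific programming bugs are **not**
emulated, and the "anchor omitted from the plot" issue is carried as a flag
only — this package's own curves always contain every anchor. Ranks use
averaged ties (rank 1 = largest AUPRC); distinct-value counting rounds to
3 decimals by default, both configurable.

The audit quantifies, on one dataset: the tie fraction; Δ1 =
AUPRC(linear ties, forced start) − AUPRC(continuous ties, limit start), the
combined inflation; Δ2 = the forced-start effect alone, measured within the
chord family it affects; Δ3 = the max − min AUPRC over seeded row shuffles
under input-order tie handling (exactly 0 for tie-free data).

A caveat the tests document: grouped-tie AP is not monotone under arbitrary
single-entity score raises. Raising a tied positive just enough to split
its block — without crossing the negative above it — can *lower* AP
(e.g. scores [0.2, 0.7, 0.2, 0.4], labels [1, 1, 1, 0]: 5/6 → 29/36);
scikit-learn's `average_precision_score` shows the same drop. Monotonicity
does hold for tie-free promotions, and that is what the property test
asserts.

## Synthetic data

The generator draws negatives from N(0, 1) and positives from
N(separation, 1), optionally quantized into `n_levels` equal-width bins
over the pooled range (bin centers become the scores), then shuffles row
order; everything is deterministic given the seed. Only the rank structure
of scores reaches any estimator, so the Gaussian family is a free choice;
quantization is what matters, because it manufactures the tie blocks that
make tools disagree. Worked examples and fixtures default to heavy
imbalance (10% positives, e.g. 50/450) and coarse scores (5–8 levels),
the regime where AUPRC is the metric of choice and tie effects are
material. What this generator does **not** emulate: correlated scores,
class-dependent score variance, calibration structure, or any specific
assay's noise — passing tests show the estimators and diagnostics are
correct on datasets with the stated tie/imbalance structure, not that any
particular real pipeline is well- or mis-evaluated.

## Oracles and test design

Brute-force references are kept free of the code paths they check:
permutation averages enumerate all C(b+c, c) label orderings of a tie
block (cap 1e5; a seeded sampling mode covers larger blocks), the
continuous closed form is checked against composite midpoint quadrature
(1e-9 agreement at 1e5–1e6 steps; the midpoint rule's O(h²) error makes
this comfortable), and AUROC is checked against direct pairwise counting.
scikit-learn serves as an additional independent route for AP and AUROC.
Problem sizes in the suite — datasets up to ~12 entities for exhaustive
checks, 1,000-case random sweeps, tie blocks up to b = c = 6 — keep every
property exhaustively checkable in seconds while covering all structural
cases (origin blocks, flat/rising/falling segments, pure-positive and
pure-negative blocks, truncation tails).

## Known limitations

- Issue flags describe documented tool behaviour; version drift in the real
  tools is not tracked, and emulation fidelity is limited to what their
  method descriptions state.
- The input-order tie policy emulates one specific stable-sort behaviour;
  other order-dependent implementations could differ.
- No confidence intervals or partial-AUC variants; ROC-space interpolation
  is straight-line only.
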