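# prcaudit

Precision-recall curves and AUPRC computed under *explicit, named*
conventions — with presets that emulate the behaviour of popular software
tools and diagnostics that explain why those tools disagree.

## The problem

In imbalanced binary classification (rare cell types, disease diagnosis,
network-edge prediction) the precision-recall curve (PRC) and the area under
it (AUPRC) are the standard performance summary. But "the" AUPRC is not one
number. Each unique classification score *t*, used as the threshold
`score ≥ t`, yields one **anchor point**

```
recall(t) = tp(t) / P        precision(t) = tp(t) / (tp(t) + fp(t))
```

and tools must decide how to connect adjacent anchors, what to do when many
entities share one score (a **tie group** contributes a single anchor), and
where the curve starts and ends. Different choices give different areas on
the same data — sometimes different enough to reorder classifiers — and
some choices are systematically optimistic.

`prcaudit` is for method developers, benchmarkers, and reviewers who need to
(a) compute AUPRC under a convention they can name, (b) reproduce or explain
the number some other tool printed, and (c) quantify how fragile a reported
AUPRC is on a given dataset.

## The four connectors

Between anchors A = (tp_A, fp_A) and B = (tp_B, fp_B), with
ΔTP = tp_B − tp_A and ΔFP = fp_B − fp_A:

- **straight line** — a chord in (recall, precision) space; area is a
  trapezoid.
- **discrete expectation** — interpolated points at the expected precision
  after `s` of the block's positives,

  ```
  precision(s) = (tp_A + s) / (tp_A + s + fp_A + s·ΔFP/ΔTP)
  ```

  at s = 0.5 (distinct scores) or s = 1, 2, … (tie blocks), joined by
  chords.
- **continuous expectation** — the same expectation integrated in closed
  form over the segment.
- **step / Average Precision (AP)** — a rectangle at the precision of B:
  `AP = Σ (R_k − R_{k−1}) · precision_k`.

Where precision falls across a tie block the expectation curve is convex, so
**linear > continuous expectation > AP** — linear tie interpolation always
flatters such classifiers. A `MethodSpec` bundles the connector choices with
the curve start policy (connector limit, forced (0, 1), or first anchor),
end policy, and tie policy (grouped vs input-order); 13 named presets
(`sklearn-PR`, `sklearn-AP`, `PRROC-continuous`, `precrec`, `PerfMeas`, …)
encode the documented behaviour of the common tools.

## Worked example

```python
from prcaudit import MethodSpec, auprc, average_precision, make_tie_block_fixture

# one confident positive, then 4 positives + 5 negatives all tied
data = make_tie_block_fixture([(1, 0), (4, 5)])

auprc(data, MethodSpec(ties_connector="linear")).value                  # 0.8000
auprc(data, MethodSpec(ties_connector="continuous_expectation")).value  # 0.6693
average_precision(data)                                                 # 0.6000
```

Three "AUPRCs" for one classifier: the linear-tie chord credits the tie
block as if precision stayed high across it (and raises a warning saying
so), the expectation integral credits what a random ordering of the tied
entities would earn, and AP only credits the block's endpoint precision.
Running `python examples/04_rank_flip.py` shows the practical consequence:
against an ordinary tie-free classifier (AP 0.679), this one wins under the
linear-tie preset and loses under the AP preset — the ranking flips with
the software. The other scripts in `examples/` walk through the basics, the
tool presets, and the dataset audit; each prints the numbers it computes
and a line on what they mean.

The command-line interface mirrors the library:

```sh
prcaudit simulate --n-pos 50 --n-neg 450 --n-levels 8 --seed 1 -o sim.tsv
prcaudit auprc --profile precrec -i sim.tsv
prcaudit audit -i sim.tsv
```

## Layout

- `src/prcaudit/anchors.py` — validation, tie grouping, anchor paths
- `src/prcaudit/interpolation.py` — the four segment connectors
- `src/prcaudit/estimators.py` — `MethodSpec`, PR curves, AUPRC/AP/AUROC
- `src/prcaudit/profiles.py` — tool presets, comparison/ranking, audit
- `src/prcaudit/oracle.py` — brute-force references used by the tests
- `src/prcaudit/synthetic.py` — score/label generators
- `src/prcaudit/io.py`, `cli.py`, `plotting.py` — I/O, CLI, optional plots
- `docs/methods.md` — the model, numerical choices, and limitations
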