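"""One dataset, four AUPRC conventions.

Builds a tiny five-entity dataset with distinct scores and computes its
AUPRC under the four anchor-connection methods. Even without any score
ties the conventions disagree, because they fill the gaps between anchor
points differently.
"""

from prcaudit import MethodSpec, auprc, auroc, validate_scored_labels

data = validate_scored_labels([0.9, 0.8, 0.7, 0.6, 0.5], [1, 1, 0, 1, 0])

recipes = {
    "straight line (trapezoids)": MethodSpec(no_ties_connector="line"),
    "discrete expectation": MethodSpec(no_ties_connector="discrete_expectation"),
    "continuous expectation": MethodSpec(no_ties_connector="continuous_expectation"),
    "step curve (Average Precision)": MethodSpec(no_ties_connector="step"),
}

print(f"{len(data)} entities, P={data.n_pos}, N={data.n_neg}")
for name, spec in recipes.items():
    print(f"  AUPRC {name:32s} {auprc(data, spec).value:.5f}")
print(f"  AUROC (identical across tools)     {auroc(data):.5f}")

# The four AUPRC values span ~0.014 on this tiny example (0.90278 for the
# straight line up to 0.91667 for AP) while AUROC is a single number —
# AUPRC's value depends on the interpolation convention, AUROC's does not.
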