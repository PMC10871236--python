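"""Two classifiers whose ranking depends on the AUPRC tool.

Classifier 'tie_heavy' scores one positive confidently and ties everything
else; 'tie_free' is a decent ordinary ranker. Linear tie interpolation
ranks tie_heavy first; Average Precision ranks it last. Pearson
correlation between the profiles' AUPRC vectors summarizes the
(dis)agreement.
"""

from prcaudit import make_tie_block_fixture, rank_classifiers

classifiers = {
    "tie_heavy": make_tie_block_fixture([(1, 0), (4, 5)]),
    "tie_free": make_tie_block_fixture([(1, 0), (0, 1)] * 5),
}
table = rank_classifiers(classifiers, ["sklearn-PR", "sklearn-AP", "PRROC-continuous"])

print("AUPRC values:")
print(table.values.round(4).to_string())
print("\nranks (1 = best):")
print(table.ranks.to_string())
print("\nPearson correlation between profiles' AUPRC vectors:")
print(table.correlations.round(3).to_string())

# The linear-ties preset and the AP preset rank the two classifiers in
# opposite orders — the same rank-flip phenomenon seen between real tools.
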