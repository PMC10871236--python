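"""Named tool-behaviour presets, method comparison, ranking, and auditing.

Ten widely used PRC/AUPRC tools differ in how they connect anchor points and
in a handful of conceptual choices, catalogued here as five issues:

1. linear interpolation across tie blocks (inflates the area whenever
   precision falls across the block);
2. forcing the curve to start at (0, 1);
3. not covering the full recall range from 0 to 1;
4. breaking score ties by input row order and treating the entities as
   distinctly scored (result depends on row order);
5. omitting anchor points from the plotted curve.

Each preset encodes one tool's connector pair, start/end policy, and tie
policy as a :class:`~prcaudit.estimators.MethodSpec`, plus the issues it
carries. Presets emulate the documented method combinations only — not
tool-specific programming bugs. Issue 5 is a declared flag: the curves this
package emits always contain every anchor point, so the omission itself is
not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchors import ScoredLabels, group_ties
from .errors import UnknownProfileError
from .estimators import MethodSpec, auprc

__all__ = [
    "ToolProfile",
    "ComparisonTable",
    "tool_profile",
    "list_profiles",
    "all_profiles",
    "compare_methods",
    "rank_classifiers",
    "audit",
]


@dataclass(frozen=True)
class ToolProfile:
    """A named AUPRC recipe with the conceptual issues it is known to carry."""

    name: str
    spec: MethodSpec
    issue_flags: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if 4 in self.issue_flags and self.spec.tie_policy != "input_order":
            raise ValueError("issue 4 requires tie_policy='input_order'")
        if 2 in self.issue_flags and self.spec.start_policy != "fixed_0_1":
            raise ValueError("issue 2 requires start_policy='fixed_0_1'")


def _p(name, no_ties, ties, start="segment_limit", end="full_recall", tie="group", flags=()):
    return ToolProfile(
        name=name,
        spec=MethodSpec(
            no_ties_connector=no_ties,
            ties_connector=ties,
            start_policy=start,
            end_policy=end,
            tie_policy=tie,
        ),
        issue_flags=frozenset(flags),
    )


# One preset per row of the tool-methods catalogue; tools offering several
# methods get one preset per method (suffixed).
_PROFILES: dict[str, ToolProfile] = {
    p.name: p
    for p in [
        _p("ROCR", "line", "discrete_expectation", start="fixed_0_1", flags=(2, 5)),
        _p("Weka", "step", "step"),
        _p("sklearn-PR", "line", "linear", start="fixed_0_1", flags=(1, 2)),
        _p("sklearn-AP", "step", "step"),
        _p(
            "PerfMeas",
            "line",
            "linear",
            start="first_anchor",
            end="truncate_at_last_distinct",
            tie="input_order",
            flags=(3, 4),
        ),
        _p("PRROC-discrete", "line", "discrete_expectation"),
        _p("PRROC-continuous", "continuous_expectation", "continuous_expectation"),
        _p("TensorFlow", "continuous_expectation", "continuous_expectation"),
        _p("precrec", "discrete_expectation", "discrete_expectation"),
        _p("TorchEval", "step", "step"),
        _p("MLeval", "line", "linear", start="first_anchor", flags=(1, 3)),
        _p("yardstick-PR", "line", "linear", start="fixed_0_1", flags=(1, 2)),
        _p("yardstick-AP", "step", "step"),
    ]
}


def tool_profile(name: str) -> ToolProfile:
    """Look up a preset by name (see :func:`list_profiles`)."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise UnknownProfileError(
            f"unknown profile {name!r}; known: {', '.join(sorted(_PROFILES))}"
        ) from None


def list_profiles() -> list[str]:
    return list(_PROFILES)


def all_profiles() -> list[ToolProfile]:
    return list(_PROFILES.values())


@dataclass(frozen=True)
class ComparisonTable:
    """AUPRC values per classifier × profile, with ranks and agreement stats.

    ``values`` rows are classifiers, columns are profiles. ``ranks`` assigns
    rank 1 to the largest AUPRC within each profile column, with tied values
    sharing averaged ranks. ``correlations`` holds the pairwise Pearson
    correlation between profiles' AUPRC vectors (meaningful with >= 2
    classifiers).
    """

    values: pd.DataFrame
    ranks: pd.DataFrame
    correlations: pd.DataFrame
    rounding: int = 3

    @property
    def n_distinct(self) -> pd.Series:
        """Distinct AUPRC values per classifier at the table's rounding."""
        return self.values.round(self.rounding).apply(lambda r: r.nunique(), axis=1)

    @property
    def spread(self) -> pd.Series:
        """max − min AUPRC per classifier across profiles."""
        return self.values.max(axis=1) - self.values.min(axis=1)

    def to_tsv(self) -> str:
        return self.values.to_csv(sep="\t", index_label="classifier")


def _as_profiles(profiles: Sequence[ToolProfile | str]) -> list[ToolProfile]:
    return [p if isinstance(p, ToolProfile) else tool_profile(p) for p in profiles]


def compare_methods(
    data: ScoredLabels,
    profiles: Sequence[ToolProfile | str] | None = None,
    rounding: int = 3,
) -> ComparisonTable:
    """AUPRC of one classifier under each profile.

    The table has a single row; its ``n_distinct`` and ``spread`` quantify
    how much the choice of tool alone moves the reported value.
    """
    profs = _as_profiles(profiles if profiles is not None else all_profiles())
    if not profs:
        raise ValueError("need at least one profile")
    row = {p.name: auprc(data, p.spec).value for p in profs}
    values = pd.DataFrame([row], index=["classifier"])
    return _table(values, rounding)


def rank_classifiers(
    datasets: Mapping[str, ScoredLabels] | Sequence[ScoredLabels],
    profiles: Sequence[ToolProfile | str] | None = None,
    rounding: int = 3,
) -> ComparisonTable:
    """Rank several classifiers under each profile and compare the rankings.

    Discordant rank columns mean the choice of AUPRC tool changes which
    classifier "wins" — the headline failure mode this package diagnoses.
    """
    if not isinstance(datasets, Mapping):
        datasets = {f"classifier_{i}": d for i, d in enumerate(datasets)}
    if len(datasets) < 2:
        raise ValueError("ranking needs at least 2 classifiers")
    profs = _as_profiles(profiles if profiles is not None else all_profiles())
    values = pd.DataFrame(
        {p.name: {k: auprc(d, p.spec).value for k, d in datasets.items()} for p in profs}
    )
    return _table(values, rounding)


def _table(values: pd.DataFrame, rounding: int) -> ComparisonTable:
    ranks = values.rank(axis=0, ascending=False, method="average")
    if len(values) >= 2 and values.shape[1] >= 1:
        correlations = values.corr(method="pearson")
    else:
        correlations = pd.DataFrame(
            np.ones((values.shape[1], values.shape[1])),
            index=values.columns,
            columns=values.columns,
        )
    return ComparisonTable(values=values, ranks=ranks, correlations=correlations, rounding=rounding)


def audit(
    data: ScoredLabels,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Quantify how susceptible one dataset is to the catalogued issues.

    Returns a dict with:

    * ``tie_fraction`` — share of entities sitting in multi-entity tie groups;
    * ``delta_linear_start`` (Δ1) — AUPRC(linear ties, forced (0,1) start)
      minus AUPRC(continuous ties, limit start): the combined inflation from
      issues 1 + 2;
    * ``delta_start_point`` (Δ2) — effect of the forced (0,1) start alone,
      holding the connectors fixed at the chord family it actually affects
      (straight line / linear ties); expectation and step areas are
      insensitive to the start vertex by construction;
    * ``delta_input_order`` (Δ3) — max − min AUPRC over seeded row shuffles
      under input-order tie handling (issue 4); 0 for tie-free data.
    """
    groups = group_ties(data)
    n = len(data)
    tie_fraction = sum(g.size for g in groups if g.size > 1) / n

    inflated = auprc(
        data, MethodSpec(ties_connector="linear", start_policy="fixed_0_1")
    ).value
    reference = auprc(data, MethodSpec()).value  # continuous ties, limit start
    delta_linear_start = inflated - reference

    delta_start = (
        auprc(data, MethodSpec(ties_connector="linear", start_policy="fixed_0_1")).value
        - auprc(data, MethodSpec(ties_connector="linear")).value
    )

    rng = np.random.default_rng(seed)
    order_spec = MethodSpec(ties_connector="linear", tie_policy="input_order")
    vals = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled = ScoredLabels(scores=data.scores[perm], labels=data.labels[perm])
        vals.append(auprc(shuffled, order_spec).value)
    delta_input_order = (max(vals) - min(vals)) if vals else 0.0

    return {
        "n_entities": n,
        "n_pos": data.n_pos,
        "n_neg": data.n_neg,
        "tie_fraction": tie_fraction,
        "delta_linear_start": delta_linear_start,
        "delta_start_point": delta_start,
        "delta_input_order": delta_input_order,
        "warnings": list(auprc(data, MethodSpec(ties_connector="linear")).warnings),
    }
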