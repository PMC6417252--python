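"""Utility-based intervention analysis on the Bayesian network.

The network becomes a decision network by clamping one chance node to a
value (an activation or inhibition action) and scoring outcomes with a
utility table over the drought gene's regulators.  An intervention uses
do-semantics: the action node's incoming edges are severed and its
distribution replaced by a point mass, leaving every other conditional
untouched.  The expected utility of action ``a`` is

    EU(a) = sum_i P(O_i | do(a)) * U(O_i)

where the outcomes O_i are the configurations of the utility scope and the
probabilities are computed by exact enumeration in the mutilated network.
Ranking all single-node activation/inhibition actions by EU identifies the
best regulator to target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .network import (
    NetworkStructure,
    ParameterSet,
    _mask,
    _states,
    joint_table,
)

__all__ = [
    "UtilityTable",
    "Intervention",
    "InterventionResult",
    "wrky_utility_table",
    "example_utility_table",
    "intervene",
    "expected_utility",
    "rank_interventions",
    "per_node_maximum",
    "report",
]


@dataclass(frozen=True)
class UtilityTable:
    """Real-valued utility for every configuration of a node scope.

    ``scope`` is the ordered list of nodes the utility depends on (the
    drought gene's regulators, not the gene itself — the target is
    marginalized out of the outcome distribution).  ``target`` names the
    downstream node the analysis aims to upregulate; intervening on it is
    disallowed.
    """

    scope: tuple[str, ...]
    entries: dict[tuple[int, ...], float]
    target: str | None = None

    def __post_init__(self) -> None:
        want = set(itertools.product((0, 1), repeat=len(self.scope)))
        if set(self.entries) != want:
            raise ValueError(
                f"utility table must cover all {len(want)} configurations "
                f"of scope {self.scope}"
            )

    @property
    def min_utility(self) -> float:
        return min(self.entries.values())

    @property
    def max_utility(self) -> float:
        return max(self.entries.values())

    def shifted(self, c: float) -> "UtilityTable":
        return replace(self, entries={k: v + c for k, v in self.entries.items()})

    def to_dict(self) -> dict:
        return {
            "scope": list(self.scope),
            "target": self.target,
            "entries": [
                {"config": list(k), "utility": v}
                for k, v in sorted(self.entries.items(), reverse=True)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityTable":
        return cls(
            scope=tuple(d["scope"]),
            entries={tuple(e["config"]): float(e["utility"]) for e in d["entries"]},
            target=d.get("target"),
        )

    @classmethod
    def from_yaml(cls, path) -> "UtilityTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def wrky_utility_table() -> UtilityTable:
    """Utilities at the drought gene H over its regulators (G, D, E).

    Best case: activators G and D on, repressor E off (utility 100); worst:
    the mirror image (utility 0).  Values are relative scores, not
    physical units.
    """
    return UtilityTable(
        scope=("G", "D", "E"),
        entries={
            (1, 1, 1): 50.0,
            (1, 1, 0): 100.0,
            (1, 0, 1): 10.0,
            (1, 0, 0): 50.0,
            (0, 1, 1): 10.0,
            (0, 1, 0): 50.0,
            (0, 0, 1): 0.0,
            (0, 0, 0): 10.0,
        },
        target="H",
    )


def example_utility_table() -> UtilityTable:
    """Utilities for the three-gene illustrative decision network: gene C
    should be active, which gene A promotes and gene B represses."""
    return UtilityTable(
        scope=("A", "B"),
        entries={(1, 0): 100.0, (1, 1): 50.0, (0, 0): 50.0, (0, 1): 0.0},
        target="C",
    )


@dataclass(frozen=True)
class Intervention:
    """Clamp one node to an action value: 1 = activate, 0 = inhibit."""

    node: str
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("action value must be 0 or 1")

    @property
    def action(self) -> str:
        return "activate" if self.value == 1 else "inhibit"

    def __str__(self) -> str:
        return f"{self.action} {self.node} ({self.node}={self.value})"


@dataclass
class InterventionResult:
    intervention: Intervention
    expected_utility: float
    outcome_distribution: dict[tuple[int, ...], float]


def intervene(
    net: NetworkStructure,
    params: ParameterSet,
    iv: Intervention,
    target: str | None = None,
) -> tuple[NetworkStructure, ParameterSet]:
    """Mutilate the network for do(node=value).

    The action node loses its incoming edges and its conditional becomes a
    point mass on the action value; all other conditionals are unchanged.
    For root nodes this coincides with conditioning on the node.
    """
    if iv.node not in net.node_ids:
        raise ValueError(f"unknown node {iv.node!r}")
    if target is not None and iv.node == target:
        raise ValueError(f"cannot intervene on the utility target {target!r}")
    new_parents = dict(net.parents)
    new_parents[iv.node] = ()
    mutilated = NetworkStructure(nodes=net.nodes, parents=new_parents)
    new_thetas = {n: dict(cfgs) for n, cfgs in params.thetas.items()}
    new_thetas[iv.node] = {(): float(iv.value)}
    new_params = ParameterSet(thetas=new_thetas, method=params.method)
    return mutilated, new_params


def expected_utility(
    net: NetworkStructure,
    params: ParameterSet,
    iv: Intervention,
    u: UtilityTable,
) -> InterventionResult:
    """EU of one action by exact enumeration in the mutilated network.

    The outcome distribution over the utility-scope configurations sums to
    one; if the action node lies inside the scope, its clamped value
    concentrates the distribution on the consistent outcomes.
    """
    for s in u.scope:
        if s not in net.node_ids:
            raise ValueError(f"utility scope node {s!r} not in network")
    mut_net, mut_params = intervene(net, params, iv, target=u.target)
    states = _states(mut_net)
    probs = joint_table(mut_net, mut_params)
    dist: dict[tuple[int, ...], float] = {}
    eu = 0.0
    for cfg in sorted(u.entries, reverse=True):
        p = float(probs[_mask(mut_net, states, dict(zip(u.scope, cfg)))].sum())
        dist[cfg] = p
        eu += p * u.entries[cfg]
    return InterventionResult(iv, float(eu), dist)


def rank_interventions(
    net: NetworkStructure,
    params: ParameterSet,
    candidates: list[str],
    u: UtilityTable,
) -> list[InterventionResult]:
    """Evaluate both actions for every candidate node and sort by EU.

    Descending EU; ties break deterministically by (node id, action value).
    """
    if not candidates:
        raise ValueError("no candidate nodes")
    results = [
        expected_utility(net, params, Intervention(node, value), u)
        for node in sorted(candidates)
        for value in (1, 0)
    ]
    results.sort(
        key=lambda r: (-r.expected_utility, r.intervention.node, r.intervention.value)
    )
    return results


def per_node_maximum(results: list[InterventionResult]) -> pd.DataFrame:
    """The per-node maximum expected utility (best of the two actions)."""
    best: dict[str, InterventionResult] = {}
    for r in results:
        node = r.intervention.node
        if node not in best or r.expected_utility > best[node].expected_utility:
            best[node] = r
    rows = [
        {
            "node": node,
            "best_action": best[node].intervention.action,
            "max_expected_utility": best[node].expected_utility,
        }
        for node in sorted(best)
    ]
    return pd.DataFrame(rows)


def report(
    results: list[InterventionResult],
    csv_path=None,
    text_path=None,
    chart_path=None,
) -> pd.DataFrame:
    """Render ranking results as a table (CSV/text) and optional bar chart.

    The chart shows one pair of bars per node: activation vs inhibition EU.
    Numeric CSVs are the authoritative artifact; the chart is cosmetic.
    """
    rows = [
        {
            "node": r.intervention.node,
            "action": r.intervention.action,
            "value": r.intervention.value,
            "expected_utility": r.expected_utility,
        }
        for r in results
    ]
    table = pd.DataFrame(rows, columns=["node", "action", "value", "expected_utility"])
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(table.to_string(index=False))
            fh.write("\n")
    if chart_path is not None and len(table):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nodes = sorted(table["node"].unique())
        act = [
            table.query("node == @n and value == 1")["expected_utility"].iloc[0]
            for n in nodes
        ]
        inh = [
            table.query("node == @n and value == 0")["expected_utility"].iloc[0]
            for n in nodes
        ]
        x = np.arange(len(nodes))
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.bar(x - 0.2, act, width=0.4, color="tab:red", label="activation")
        ax.bar(x + 0.2, inh, width=0.4, color="black", label="inhibition")
        ax.set_xticks(x, nodes)
        ax.set_ylabel("expected utility")
        ax.set_xlabel("intervention node")
        ax.legend()
        fig.tight_layout()
        fig.savefig(chart_path)
        plt.close(fig)
    return table
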