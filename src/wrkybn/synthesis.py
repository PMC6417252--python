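"""Rule-based synthesis of protein-complex node values.

Expression data exist only for the genes/transcription factors (nodes A, B,
F, H).  The protein complexes C, D, E and G carry no expression signal, so
their binary states are synthesized from the observed columns using the
dependency structure of the network: configurations where the observed
neighbours fully determine the complex's state are set deterministically;
mixed configurations are assigned a value ``v`` with a probability drawn
uniformly from a discrete set (default {0.6, 0.7, 0.8, 0.9, 1.0}, mean 0.8),
and ``1 - v`` otherwise.

The draw of the assignment probability is fresh per observation by default
(one draw per assignment event); ``per_column=True`` draws a single
probability per node instead.  Each complex node consumes an independent,
node-keyed random stream derived from the run seed, so the order in which
columns are synthesized never changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (
    COMPLEX_NODES,
    BinaryDataset,
    NetworkStructure,
    NodeSpec,
    ParameterSet,
    build_wrky_network,
    forward_sample,
)

__all__ = [
    "Rule",
    "ComplexRuleTable",
    "AssignmentProbabilitySet",
    "WRKY_RULES",
    "synthesize_complex_column",
    "synthesize_all",
    "generate_composite",
]


@dataclass(frozen=True)
class Rule:
    """Outcome for one configuration: deterministic value or Assign(value)."""

    value: int
    deterministic: bool

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("rule value must be 0 or 1")


def det(value: int) -> Rule:
    return Rule(value, True)


def assign(value: int) -> Rule:
    return Rule(value, False)


@dataclass(frozen=True)
class ComplexRuleTable:
    """Synthesis rules for one complex node.

    ``conditioners`` are the observed nodes (the complex's parents and
    children in the network) whose joint configuration selects a
    :class:`Rule`.  Every configuration of the conditioners must be covered.
    """

    node: str
    conditioners: tuple[str, ...]
    rules: dict[tuple[int, ...], Rule]

    def __post_init__(self) -> None:
        want = 2 ** len(self.conditioners)
        if len(self.rules) != want:
            raise ValueError(
                f"rule table for {self.node} must cover all {want} "
                f"configurations of {self.conditioners}"
            )

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "conditioners": list(self.conditioners),
            "rules": [
                {
                    "config": list(cfg),
                    "value": r.value,
                    "deterministic": r.deterministic,
                }
                for cfg, r in sorted(self.rules.items(), reverse=True)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComplexRuleTable":
        return cls(
            node=d["node"],
            conditioners=tuple(d["conditioners"]),
            rules={
                tuple(r["config"]): Rule(int(r["value"]), bool(r["deterministic"]))
                for r in d["rules"]
            },
        )


#: The WRKY rule tables.  D is conditioned on its parent A and child H
#: (A activates D, D activates H), E on B and H (B activates E, E represses
#: H), G on F and H, and C on its parents A, B and child F.
WRKY_RULES: dict[str, ComplexRuleTable] = {
    "D": ComplexRuleTable(
        "D",
        ("A", "H"),
        {(1, 1): det(1), (1, 0): assign(1), (0, 1): assign(0), (0, 0): det(0)},
    ),
    "E": ComplexRuleTable(
        "E",
        ("B", "H"),
        {(1, 1): assign(1), (1, 0): det(1), (0, 1): det(0), (0, 0): assign(0)},
    ),
    "G": ComplexRuleTable(
        "G",
        ("F", "H"),
        {(1, 1): det(1), (1, 0): assign(1), (0, 1): assign(0), (0, 0): det(0)},
    ),
    "C": ComplexRuleTable(
        "C",
        ("A", "B", "F"),
        {
            (0, 0, 0): det(0),
            (0, 0, 1): assign(0),
            (0, 1, 0): assign(0),
            (0, 1, 1): assign(1),
            (1, 0, 0): assign(0),
            (1, 1, 0): assign(1),
            (1, 0, 1): assign(1),
            (1, 1, 1): det(1),
        },
    ),
}


@dataclass(frozen=True)
class AssignmentProbabilitySet:
    """Discrete probabilities used for probabilistic assignment, each
    equally likely; members must exceed 0.5 so the assigned value is always
    the more probable one."""

    values: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("probability set must be non-empty")
        for p in self.values:
            if not (0.5 < p <= 1.0):
                raise ValueError(f"assignment probability {p} not in (0.5, 1.0]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


# fixed per-node stream ids so draws are independent of synthesis order
_NODE_STREAM = {node: i for i, node in enumerate(sorted(COMPLEX_NODES))}


def _node_rng(seed: int, node: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _NODE_STREAM.get(node, ord(node))])


def synthesize_complex_column(
    data: BinaryDataset,
    node: NodeSpec | str,
    rules: ComplexRuleTable,
    probs: AssignmentProbabilitySet | None = None,
    seed: int = 0,
    per_column: bool = False,
) -> BinaryDataset:
    """Fill one complex node's column from its rule table.

    Deterministic rows are set exactly; Assign(v) rows get ``v`` with a
    probability drawn uniformly from ``probs`` (fresh draw per observation
    unless ``per_column``), else ``1 - v``.  The new column is tagged
    ``synthetic``.  Raises if a conditioning column is missing/incomplete or
    if the target column already holds values (no silent overwrite).
    """
    node_id = node.id if isinstance(node, NodeSpec) else node
    probs = probs or AssignmentProbabilitySet()
    if node_id in data.frame.columns and not data.frame[node_id].isna().all():
        raise ValueError(f"column {node_id} already present; refusing to overwrite")
    for c in rules.conditioners:
        if c not in data.frame.columns:
            raise ValueError(f"conditioning column {c} missing for node {node_id}")
        if data.frame[c].isna().any():
            raise ValueError(f"conditioning column {c} has missing values")

    cond = data.frame[list(rules.conditioners)].to_numpy(dtype=int)
    n = len(cond)
    out = np.empty(n, dtype=float)
    rng = _node_rng(seed, node_id)
    p_col = rng.choice(probs.values) if per_column else None
    for i in range(n):
        rule = rules.rules[tuple(cond[i])]
        if rule.deterministic:
            out[i] = rule.value
        else:
            p = p_col if per_column else rng.choice(probs.values)
            out[i] = rule.value if rng.random() < p else 1 - rule.value
    return data.with_column(node_id, out, tag="synthetic")


def synthesize_all(
    data: BinaryDataset,
    net: NetworkStructure | None = None,
    seed: int = 0,
    probs: AssignmentProbabilitySet | None = None,
    rules: dict[str, ComplexRuleTable] | None = None,
    per_column: bool = False,
) -> BinaryDataset:
    """Fill all complex-node columns (C, D, E, G) from their rule tables.

    Requires the observed columns A, B, F, H to be complete.  Synthesis
    order is irrelevant: every complex node conditions only on observed
    non-complex columns, and each uses its own random stream.
    """
    net = net or build_wrky_network()
    rules = rules or WRKY_RULES
    out = data
    for node in sorted(rules):
        out = synthesize_complex_column(
            out, node, rules[node], probs=probs, seed=seed, per_column=per_column
        )
    return out


def generate_composite(
    net: NetworkStructure,
    params: ParameterSet,
    n: int,
    seed: int = 0,
    probs: AssignmentProbabilitySet | None = None,
) -> tuple[BinaryDataset, BinaryDataset]:
    """End-to-end simulation fixture.

    Forward-samples ``n`` complete observations from ``params`` (the ground
    truth), then rebuilds a pipeline-style dataset: the gene columns A, B, F,
    H are kept as 'real' observations and the complex columns are re-derived
    by rule-based synthesis.  Returns ``(truth, pipeline)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ss = np.random.SeedSequence(seed)
    sample_seed, synth_seed = ss.spawn(2)
    truth = forward_sample(net, params, n, np.random.default_rng(sample_seed))
    observed_cols = [c for c in truth.columns() if c not in COMPLEX_NODES]
    observed = BinaryDataset(
        truth.frame[observed_cols].copy(),
        {c: "real" for c in observed_cols},
    )
    synth_int_seed = int(synth_seed.generate_state(1)[0] % (2**31))
    pipeline = synthesize_all(observed, net, seed=synth_int_seed, probs=probs)
    return truth, pipeline
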