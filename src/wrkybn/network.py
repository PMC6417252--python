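"""Discrete Bayesian-network structure and exact inference over binary nodes.

The WRKY drought-response pathway is modelled as an eight-node binary
Bayesian network.  Nodes ``A``–``H`` are genes, transcription factors or
protein complexes; state 1 means activation, 0 inhibition.  The joint
distribution factorizes into one Bernoulli conditional per node given its
parents.  The network is small (2^8 = 256 joint states), so all inference is
exact full enumeration — message passing is not applicable anyway because the
moralized graph is loopy and not singly connected.

All iteration is over node ids in sorted order, so results are bit-stable
across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NodeSpec",
    "NetworkStructure",
    "ParameterSet",
    "BinaryDataset",
    "ZeroEvidenceError",
    "build_wrky_network",
    "build_example_network",
    "validate_structure",
    "joint_probability",
    "joint_table",
    "marginal",
    "forward_sample",
    "wrky_reference_parameters",
    "table7_bayesian_parameters",
    "table7_mle_parameters",
]

#: Node ids of the WRKY network whose values are protein complexes
#: (no expression data exists for them; they are synthesized from rules).
COMPLEX_NODES = ("C", "D", "E", "G")

#: Default biological labels.  The single letter is the node identity;
#: labels are display metadata and can be overridden from config.
WRKY_LABELS = {
    "A": "WRKY18",
    "B": "WRKY40",
    "C": "WRKY18-40 complex",
    "D": "WRKY18-18 complex",
    "E": "WRKY40-40 complex",
    "F": "WRKY60",
    "G": "WRKY60-60 complex",
    "H": "drought-response gene",
}

#: Parent sets of the WRKY network (child -> sorted parents).
WRKY_PARENTS = {
    "A": (),
    "B": (),
    "C": ("A", "B"),
    "D": ("A",),
    "E": ("B",),
    "F": ("C",),
    "G": ("F",),
    "H": ("D", "E", "G"),
}


class ZeroEvidenceError(ValueError):
    """Raised when conditioning on evidence of probability zero."""


@dataclass(frozen=True)
class NodeSpec:
    """One binary node: identity, display label, and complex/gene role."""

    id: str
    label: str = ""
    is_complex: bool = False

    def __post_init__(self) -> None:
        if not (len(self.id) == 1 and self.id.isalpha()):
            raise ValueError(f"node id must be a single letter, got {self.id!r}")


@dataclass(frozen=True)
class NetworkStructure:
    """A directed acyclic graph over binary nodes.

    ``parents`` maps each node id to its (sorted) parent ids; ``nodes`` holds
    the :class:`NodeSpec` metadata.  Construction validates acyclicity.
    """

    nodes: tuple[NodeSpec, ...]
    parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        known = set(ids)
        for child, pas in self.parents.items():
            if child not in known:
                raise ValueError(f"edge child {child!r} is not a declared node")
            for p in pas:
                if p not in known:
                    raise ValueError(f"parent {p!r} of {child!r} is not a declared node")
        object.__setattr__(
            self,
            "parents",
            {i: tuple(sorted(self.parents.get(i, ()))) for i in ids},
        )
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"network contains a cycle: {cycle}")

    # -- views -------------------------------------------------------------
    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(sorted(n.id for n in self.nodes))

    def spec(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.id for n in self.nodes)
        for child, pas in self.parents.items():
            g.add_edges_from((p, child) for p in pas)
        return g

    def topological_order(self) -> list[str]:
        # lexicographic tie-break for determinism
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "label": n.label, "is_complex": n.is_complex}
                for n in sorted(self.nodes, key=lambda n: n.id)
            ],
            "parents": {i: list(self.parents[i]) for i in self.node_ids},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkStructure":
        nodes = tuple(
            NodeSpec(n["id"], n.get("label", ""), bool(n.get("is_complex", False)))
            for n in d["nodes"]
        )
        parents = {k: tuple(v) for k, v in d.get("parents", {}).items()}
        return cls(nodes=nodes, parents=parents)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkStructure":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ParameterSet:
    """Per-node activation probabilities for every parent configuration.

    ``thetas[X][cfg]`` is P(X=1 | Pa(X)=cfg) where ``cfg`` is a tuple of 0/1
    values ordered like ``structure.parents[X]`` (sorted parent ids).  When
    estimated by Beta-Binomial updating, ``posterior[X][cfg]`` holds the
    posterior shape pair (alpha', beta') and ``counts[X][cfg]`` the sufficient
    counts (n, k).  MLE entries with no observations are listed in
    ``undefined`` and carry theta = NaN.
    """

    thetas: dict[str, dict[tuple[int, ...], float]]
    posterior: dict[str, dict[tuple[int, ...], tuple[float, float]]] | None = None
    counts: dict[str, dict[tuple[int, ...], tuple[int, int]]] | None = None
    undefined: set[tuple[str, tuple[int, ...]]] = field(default_factory=set)
    method: str = ""

    def validate(self, net: NetworkStructure) -> None:
        for node in net.node_ids:
            pas = net.parents[node]
            entries = self.thetas.get(node)
            if entries is None:
                raise ValueError(f"no parameters for node {node}")
            want = set(itertools.product((0, 1), repeat=len(pas)))
            if set(entries) != want:
                raise ValueError(
                    f"node {node}: expected {len(want)} parent configurations, "
                    f"got {sorted(entries)}"
                )
            for cfg, th in entries.items():
                if (node, cfg) in self.undefined:
                    continue
                if not (0.0 <= th <= 1.0):
                    raise ValueError(f"theta out of [0,1] for {node}|{cfg}: {th}")
        if self.posterior is not None:
            for node, d in self.posterior.items():
                for cfg, (a, b) in d.items():
                    if a <= 0 or b <= 0:
                        raise ValueError(f"non-positive Beta shapes for {node}|{cfg}")

    def theta(self, node: str, cfg: tuple[int, ...]) -> float:
        return self.thetas[node][cfg]

    def n_entries(self) -> int:
        return sum(len(v) for v in self.thetas.values())

    def entry_labels(self, net: NetworkStructure) -> list[tuple[str, str, tuple[int, ...]]]:
        """Rows as (label, node, cfg) in the conventional table layout,
        e.g. ``P(C1 |A1,B0)`` for P(C=1 | A=1, B=0)."""
        rows = []
        for node in net.node_ids:
            pas = net.parents[node]
            for cfg in sorted(self.thetas[node], reverse=True):
                if pas:
                    cond = ",".join(f"{p}{v}" for p, v in zip(pas, cfg))
                    label = f"P({node}1 |{cond})"
                else:
                    label = f"P({node}1)"
                rows.append((label, node, cfg))
        return rows

    def to_frame(self, net: NetworkStructure) -> pd.DataFrame:
        rows = []
        for label, node, cfg in self.entry_labels(net):
            rec = {"entry": label, "node": node, "theta": self.thetas[node][cfg]}
            if self.counts is not None:
                n, k = self.counts[node][cfg]
                rec.update(n=n, k=k)
            if self.posterior is not None:
                a, b = self.posterior[node][cfg]
                rec.update(alpha_post=a, beta_post=b)
            rec["undefined"] = (node, cfg) in self.undefined
            rows.append(rec)
        return pd.DataFrame(rows)


@dataclass
class BinaryDataset:
    """Observations x nodes matrix of {0,1} values, possibly with missing
    entries for complex nodes before synthesis.

    ``frame`` uses float storage so missing entries are NaN; ``provenance``
    tags each column as ``real`` / ``synthetic`` / ``sampled``.
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-binary value at row {bad[0]}, column "
                f"{self.frame.columns[bad[1]]!r}"
            )

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def is_complete(self) -> bool:
        return not self.frame.isna().any().any()

    def column_values(self, node: str) -> np.ndarray:
        return self.frame[node].to_numpy(dtype=float)

    def with_column(self, node: str, values: np.ndarray, tag: str) -> "BinaryDataset":
        frame = self.frame.copy()
        frame[node] = np.asarray(values, dtype=float)
        frame = frame[sorted(frame.columns)]
        prov = dict(self.provenance)
        prov[node] = tag
        return BinaryDataset(frame, prov)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for col in self.frame.columns:
                fh.write(f"# provenance {col}: {self.provenance.get(col, 'unknown')}\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "BinaryDataset":
        prov: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# provenance "):
                rest = line[len("# provenance "):].strip()
                col, tag = rest.split(":", 1)
                prov[col.strip()] = tag.strip()
            else:
                body.append(line)
        from io import StringIO

        frame = pd.read_csv(StringIO("".join(body)))
        return cls(frame, prov)


# ---------------------------------------------------------------------------
# construction


def build_wrky_network(labels: dict[str, str] | None = None) -> NetworkStructure:
    """The eight-node WRKY drought-pathway network.

    Roots A (WRKY18) and B (WRKY40) are ABA-induced transcription factors;
    C, D, E, G are protein complexes; F is WRKY60; H is the downstream
    drought-response gene with parents D, E and G.  ``labels`` overrides the
    default display names.
    """
    lab = dict(WRKY_LABELS)
    if labels:
        lab.update(labels)
    nodes = tuple(
        NodeSpec(i, lab.get(i, ""), is_complex=i in COMPLEX_NODES)
        for i in sorted(WRKY_PARENTS)
    )
    return NetworkStructure(nodes=nodes, parents=dict(WRKY_PARENTS))


def build_example_network() -> tuple[NetworkStructure, ParameterSet]:
    """The three-gene illustrative decision network.

    Roots A and B with P(A=1)=0.7, P(B=1)=0.2 regulate gene C (A activates,
    B inhibits).  C's conditional is not used by the utility analysis (the
    utility scope is (A, B)); a plausible activating/inhibiting CPT is
    supplied so the joint distribution is fully specified.
    """
    nodes = (
        NodeSpec("A", "gene A"),
        NodeSpec("B", "gene B"),
        NodeSpec("C", "gene C"),
    )
    net = NetworkStructure(nodes=nodes, parents={"A": (), "B": (), "C": ("A", "B")})
    params = ParameterSet(
        thetas={
            "A": {(): 0.7},
            "B": {(): 0.2},
            "C": {(1, 0): 0.9, (1, 1): 0.5, (0, 0): 0.5, (0, 1): 0.1},
        },
        method="illustrative",
    )
    params.validate(net)
    return net, params


def table7_bayesian_parameters(theta_h: dict[tuple[int, int, int], float] | None = None) -> ParameterSet:
    """The published Beta-Binomial posterior-mean estimates for the WRKY net.

    The published table reports no conditional for the sink H; H is
    marginalized out of every expected-utility computation, so any valid CPT
    leaves the intervention analysis unchanged.  A neutral 0.5 CPT is used
    unless ``theta_h`` supplies one (keys ordered (D, E, G))."""
    thetas: dict[str, dict[tuple[int, ...], float]] = {
        "A": {(): 0.50},
        "B": {(): 0.466},
        "C": {(1, 1): 0.905, (0, 1): 0.625, (1, 0): 0.60, (0, 0): 0.13},
        "D": {(1,): 0.983, (0,): 0.10},
        "E": {(1,): 0.857, (0,): 0.093},
        "F": {(1,): 0.766, (0,): 0.196},
        "G": {(1,): 0.867, (0,): 0.117},
        "H": {cfg: 0.5 for cfg in itertools.product((0, 1), repeat=3)},
    }
    if theta_h is not None:
        thetas["H"] = dict(theta_h)
    ps = ParameterSet(thetas=thetas, method="bayesian (published)")
    ps.validate(build_wrky_network())
    return ps


def table7_mle_parameters(theta_h: dict[tuple[int, int, int], float] | None = None) -> ParameterSet:
    """The published maximum-likelihood estimates (H handled as above)."""
    thetas: dict[str, dict[tuple[int, ...], float]] = {
        "A": {(): 0.50},
        "B": {(): 0.465},
        "C": {(1, 1): 0.925, (0, 1): 0.645, (1, 0): 0.611, (0, 0): 0.113},
        "D": {(1,): 1.0, (0,): 0.086},
        "E": {(1,): 0.870, (0,): 0.080},
        "F": {(1,): 0.774, (0,): 0.185},
        "G": {(1,): 0.879, (0,): 0.103},
        "H": {cfg: 0.5 for cfg in itertools.product((0, 1), repeat=3)},
    }
    if theta_h is not None:
        thetas["H"] = dict(theta_h)
    ps = ParameterSet(thetas=thetas, method="mle (published)")
    ps.validate(build_wrky_network())
    return ps


def wrky_reference_parameters() -> ParameterSet:
    """A complete ground-truth parameter set for simulation fixtures.

    Uses the published Beta-Binomial estimates for A–G and a biologically
    motivated CPT for H: the drought gene is most likely active when its
    activators D and G are on and its repressor E is off, least likely in the
    mirror-image state.  Keys for H are ordered (D, E, G)."""
    theta_h = {
        # (D, E, G): P(H=1)
        (1, 0, 1): 0.95,
        (1, 0, 0): 0.70,
        (0, 0, 1): 0.70,
        (1, 1, 1): 0.55,
        (0, 0, 0): 0.30,
        (1, 1, 0): 0.35,
        (0, 1, 1): 0.35,
        (0, 1, 0): 0.05,
    }
    ps = table7_bayesian_parameters(theta_h=theta_h)
    ps.method = "reference (simulation ground truth)"
    return ps


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    acyclic: bool
    weakly_connected: bool
    isolated_nodes: list[str]
    no_path_to_target: list[str]
    warnings: list[str]

    @property
    def valid(self) -> bool:
        return self.acyclic


def validate_structure(net: NetworkStructure, target: str | None = "H") -> ValidationReport:
    """Structural checks: acyclicity (raised at construction already),
    connectedness, and nodes with no directed path to the utility target."""
    g = net.to_networkx()
    acyclic = nx.is_directed_acyclic_graph(g)
    if not acyclic:  # defensive; NetworkStructure cannot be built cyclic
        raise ValueError("network contains a cycle")
    weakly = nx.is_weakly_connected(g) if len(g) else True
    isolated = sorted(nx.isolates(g))
    unreachable: list[str] = []
    if target is not None and target in g:
        for n in sorted(g.nodes):
            if n == target:
                continue
            if not nx.has_path(g, n, target):
                unreachable.append(n)
    warnings = []
    if isolated:
        warnings.append(f"isolated nodes: {', '.join(isolated)}")
    if unreachable:
        warnings.append(f"no directed path to {target}: {', '.join(unreachable)}")
    return ValidationReport(acyclic, weakly, isolated, unreachable, warnings)


# ---------------------------------------------------------------------------
# exact inference by full enumeration


def _states(net: NetworkStructure) -> np.ndarray:
    """All 2^N full assignments as an array of shape (2^N, N), columns in
    sorted node-id order, rows in binary counting order."""
    n = len(net.node_ids)
    bits = np.arange(2**n, dtype=np.int64)
    return (bits[:, None] >> np.arange(n - 1, -1, -1)) & 1


def joint_table(net: NetworkStructure, params: ParameterSet) -> np.ndarray:
    """Joint probability of every full assignment (2^N vector)."""
    ids = net.node_ids
    idx = {node: j for j, node in enumerate(ids)}
    states = _states(net)
    probs = np.ones(len(states))
    for node in ids:
        pas = net.parents[node]
        th = np.empty(len(states))
        pa_cols = states[:, [idx[p] for p in pas]] if pas else None
        for cfg, theta in params.thetas[node].items():
            if pas:
                mask = (pa_cols == np.array(cfg)).all(axis=1)
            else:
                mask = np.ones(len(states), dtype=bool)
            th[mask] = theta
        x = states[:, idx[node]]
        probs *= np.where(x == 1, th, 1.0 - th)
    return probs


def joint_probability(
    net: NetworkStructure, params: ParameterSet, assignment: dict[str, int]
) -> float:
    """P(x_1, ..., x_N) under the factorization, for a full assignment."""
    missing = set(net.node_ids) - set(assignment)
    if missing:
        raise ValueError(f"assignment incomplete, missing nodes {sorted(missing)}")
    _check_binary(assignment)
    p = 1.0
    for node in net.node_ids:
        cfg = tuple(assignment[pa] for pa in net.parents[node])
        theta = params.thetas[node][cfg]
        p *= theta if assignment[node] == 1 else 1.0 - theta
    return p


def _check_binary(assignment: dict[str, int]) -> None:
    for k, v in assignment.items():
        if v not in (0, 1):
            raise ValueError(f"assignment value for {k} must be 0 or 1, got {v!r}")


def _mask(net: NetworkStructure, states: np.ndarray, partial: dict[str, int]) -> np.ndarray:
    idx = {node: j for j, node in enumerate(net.node_ids)}
    m = np.ones(len(states), dtype=bool)
    for node, v in partial.items():
        m &= states[:, idx[node]] == v
    return m


def marginal(
    net: NetworkStructure,
    params: ParameterSet,
    query: dict[str, int],
    evidence: dict[str, int] | None = None,
) -> float:
    """Exact P(query | evidence) by summation over the full joint table."""
    evidence = evidence or {}
    overlap = set(query) & set(evidence)
    if overlap:
        raise ValueError(f"query and evidence overlap on {sorted(overlap)}")
    _check_binary(query)
    _check_binary(evidence)
    states = _states(net)
    probs = joint_table(net, params)
    p_ev = probs[_mask(net, states, evidence)].sum() if evidence else 1.0
    if p_ev <= 0.0:
        raise ZeroEvidenceError(f"evidence {evidence} has probability zero")
    joint = probs[_mask(net, states, {**query, **evidence})].sum()
    return float(joint / p_ev)


# ---------------------------------------------------------------------------
# forward sampling


def forward_sample(
    net: NetworkStructure,
    params: ParameterSet,
    n: int,
    seed: int | np.random.Generator,
    provenance: str = "sampled",
) -> BinaryDataset:
    """Draw ``n`` independent full assignments in topological order."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = net.node_ids
    cols = {node: np.empty(n, dtype=float) for node in ids}
    for node in net.topological_order():
        pas = net.parents[node]
        u = rng.random(n)
        if not pas:
            theta = params.thetas[node][()]
            cols[node][:] = (u < theta).astype(float)
        else:
            pa_vals = np.stack([cols[p] for p in pas], axis=1).astype(int)
            th = np.empty(n)
            for cfg, theta in params.thetas[node].items():
                mask = (pa_vals == np.array(cfg)).all(axis=1)
                th[mask] = theta
            cols[node][:] = (u < th).astype(float)
    frame = pd.DataFrame({node: cols[node] for node in ids})
    return BinaryDataset(frame, {node: provenance for node in ids})
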