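"""Shared fixtures and an independent brute-force inference oracle.

The oracle works on plain dicts (parents map + theta map) with pure-Python
loops over all full assignments, deliberately sharing no code with the
package's vectorized enumeration engine.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from wrkybn import (
    build_wrky_network,
    wrky_reference_parameters,
)
from wrkybn.network import ParameterSet


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_joint(parents, thetas, assignment):
    """P(full assignment) = product of per-node Bernoulli conditionals."""
    p = 1.0
    for node, pas in parents.items():
        cfg = tuple(assignment[q] for q in pas)
        th = thetas[node][cfg]
        p *= th if assignment[node] == 1 else 1.0 - th
    return p


def oracle_enumerate(parents, thetas):
    """All full assignments with their joint probabilities."""
    ids = sorted(parents)
    out = []
    for vals in itertools.product((0, 1), repeat=len(ids)):
        a = dict(zip(ids, vals))
        out.append((a, oracle_joint(parents, thetas, a)))
    return out

def oracle_marginal(parents, thetas, query, evidence=None):
    evidence = evidence or {}
    num = den = 0.0
    for a, p in oracle_enumerate(parents, thetas):
        if all(a[k] == v for k, v in evidence.items()):
            den += p
            if all(a[k] == v for k, v in query.items()):
                num += p
    return num / den


def oracle_expected_utility(parents, thetas, node, value, scope, utilities):
    """EU of do(node=value): sever the node's parents, clamp it, enumerate."""
    mut_parents = dict(parents)
    mut_parents[node] = ()
    mut_thetas = {k: dict(v) for k, v in thetas.items()}
    mut_thetas[node] = {(): float(value)}
    eu = 0.0
    for a, p in oracle_enumerate(mut_parents, mut_thetas):
        cfg = tuple(a[s] for s in scope)
        eu += p * utilities[cfg]
    return eu


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def wrky_net():
    return build_wrky_network()


@pytest.fixture(scope="session")
def ref_params():
    return wrky_reference_parameters()


def random_parameter_set(net, rng) -> ParameterSet:
    thetas = {
        node: {
            cfg: float(rng.uniform(0.02, 0.98))
            for cfg in itertools.product((0, 1), repeat=len(net.parents[node]))
        }
        for node in net.node_ids
    }
    return ParameterSet(thetas=thetas, method="random")


def as_plain(net, params):
    """Plain (parents, thetas) dicts for the oracle."""
    return dict(net.parents), {n: dict(c) for n, c in params.thetas.items()}
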