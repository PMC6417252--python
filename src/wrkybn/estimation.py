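"""Parameter estimation for the binary Bayesian network.

Each node's conditional probability of activation is a Bernoulli parameter
per parent configuration.  Two estimators are provided:

* Beta-Binomial Bayesian updating: with prior Beta(alpha, beta) and counts
  (n, k) for a parent configuration, the posterior is
  Beta(alpha + k, beta + n - k) and the point estimate is its mean
  (alpha + k) / (alpha + beta + n).  With the default flat Beta(1, 1) prior
  this is the Laplace-smoothed (k + 1)/(n + 2), strictly inside (0, 1) for
  any finite data — a zero estimate can only arise from true non-occurrence
  in the limit.
* Maximum likelihood: k / n, which can reach the boundary {0, 1} and is
  undefined for unobserved parent configurations (reported as such, never
  silently zeroed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BinaryDataset, NetworkStructure, ParameterSet

__all__ = [
    "SufficientCounts",
    "count_sufficient_stats",
    "bayesian_estimate",
    "mle_estimate",
    "compare_estimates",
    "format_parameter_table",
]

BetaPrior = tuple[float, float]


@dataclass
class SufficientCounts:
    """Per node and parent configuration: n observations, k with node=1."""

    structure: NetworkStructure
    counts: dict[str, dict[tuple[int, ...], tuple[int, int]]]
    n_obs: int

    def entry(self, node: str, cfg: tuple[int, ...]) -> tuple[int, int]:
        return self.counts[node][cfg]


def count_sufficient_stats(data: BinaryDataset, net: NetworkStructure) -> SufficientCounts:
    """Tally (n, k) for every node and parent configuration.

    The dataset must be complete; run synthesis for the complex nodes first.
    Conservation holds by construction: the per-node n's sum to the number
    of observations.
    """
    if not data.is_complete():
        missing = [c for c in data.frame.columns if data.frame[c].isna().any()]
        raise ValueError(
            f"dataset has missing values in columns {missing}; "
            "run synthesize_all() before estimation"
        )
    for node in net.node_ids:
        if node not in data.frame.columns:
            raise ValueError(f"dataset lacks a column for node {node}")
    values = {node: data.frame[node].to_numpy(dtype=int) for node in net.node_ids}
    counts: dict[str, dict[tuple[int, ...], tuple[int, int]]] = {}
    for node in net.node_ids:
        pas = net.parents[node]
        x = values[node]
        node_counts: dict[tuple[int, ...], tuple[int, int]] = {}
        for cfg in itertools.product((0, 1), repeat=len(pas)):
            if pas:
                mask = np.ones(len(x), dtype=bool)
                for p, v in zip(pas, cfg):
                    mask &= values[p] == v
            else:
                mask = np.ones(len(x), dtype=bool)
            n = int(mask.sum())
            k = int(x[mask].sum())
            node_counts[cfg] = (n, k)
        counts[node] = node_counts
    return SufficientCounts(net, counts, data.n_obs)


def _validate_prior(prior: BetaPrior) -> None:
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError(f"Beta prior shapes must be positive, got ({a}, {b})")


def bayesian_estimate(
    counts: SufficientCounts,
    prior: BetaPrior | dict[str, dict[tuple[int, ...], BetaPrior]] = (1.0, 1.0),
) -> ParameterSet:
    """Posterior-mean estimates under conjugate Beta-Binomial updating.

    ``prior`` is either one (alpha, beta) pair applied to every entry, or a
    per-node/per-configuration mapping for informative priors.
    """
    per_entry = isinstance(prior, dict)
    if not per_entry:
        _validate_prior(prior)
    thetas: dict[str, dict[tuple[int, ...], float]] = {}
    posterior: dict[str, dict[tuple[int, ...], tuple[float, float]]] = {}
    for node, node_counts in counts.counts.items():
        thetas[node] = {}
        posterior[node] = {}
        for cfg, (n, k) in node_counts.items():
            a, b = prior[node][cfg] if per_entry else prior
            if per_entry:
                _validate_prior((a, b))
            a_post, b_post = a + k, b + (n - k)
            thetas[node][cfg] = a_post / (a_post + b_post)
            posterior[node][cfg] = (a_post, b_post)
    ps = ParameterSet(
        thetas=thetas,
        posterior=posterior,
        counts={n: dict(c) for n, c in counts.counts.items()},
        method="bayesian",
    )
    ps.validate(counts.structure)
    return ps


def mle_estimate(counts: SufficientCounts) -> ParameterSet:
    """Maximum-likelihood estimates k/n; unobserved configurations (n=0) are
    flagged undefined and carry NaN."""
    thetas: dict[str, dict[tuple[int, ...], float]] = {}
    undefined: set[tuple[str, tuple[int, ...]]] = set()
    for node, node_counts in counts.counts.items():
        thetas[node] = {}
        for cfg, (n, k) in node_counts.items():
            if n == 0:
                thetas[node][cfg] = float("nan")
                undefined.add((node, cfg))
            else:
                thetas[node][cfg] = k / n
    ps = ParameterSet(
        thetas=thetas,
        counts={n: dict(c) for n, c in counts.counts.items()},
        undefined=undefined,
        method="mle",
    )
    ps.validate(counts.structure)
    return ps


@dataclass
class EstimateComparison:
    table: pd.DataFrame
    max_difference: float


def compare_estimates(
    bayes: ParameterSet, mle: ParameterSet, net: NetworkStructure
) -> EstimateComparison:
    """Entry-by-entry comparison of the two estimators.

    Rows follow the conventional table layout (``P(A1)``, ``P(C1 |A1,B1)``,
    ...).  Undefined MLE entries yield NaN differences and are excluded from
    the maximum.
    """
    if set(bayes.thetas) != set(mle.thetas):
        raise ValueError("parameter sets cover different nodes")
    for node in bayes.thetas:
        if set(bayes.thetas[node]) != set(mle.thetas[node]):
            raise ValueError(f"parameter sets disagree on configurations of {node}")
    rows = []
    for label, node, cfg in bayes.entry_labels(net):
        tb = bayes.thetas[node][cfg]
        tm = mle.thetas[node][cfg]
        rows.append(
            {
                "entry": label,
                "bayesian": tb,
                "mle": tm,
                "abs_difference": abs(tb - tm),
            }
        )
    table = pd.DataFrame(rows)
    finite = table["abs_difference"].dropna()
    max_diff = float(finite.max()) if len(finite) else float("nan")
    return EstimateComparison(table, max_diff)


def format_parameter_table(
    net: NetworkStructure,
    bayes: ParameterSet | None = None,
    mle: ParameterSet | None = None,
    digits: int = 3,
) -> pd.DataFrame:
    """Two-column local-probability table (one column per method)."""
    ref = bayes or mle
    if ref is None:
        raise ValueError("at least one parameter set required")
    rows = []
    for label, node, cfg in ref.entry_labels(net):
        rec: dict[str, object] = {"Local Probabilities": label}
        if bayes is not None:
            rec["Bayesian Approach"] = round(bayes.thetas[node][cfg], digits)
        if mle is not None:
            v = mle.thetas[node][cfg]
            rec["MLE Approach"] = round(v, digits) if np.isfinite(v) else "undefined"
        rows.append(rec)
    return pd.DataFrame(rows)
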