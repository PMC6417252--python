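"""End-to-end orchestration: preprocess -> synthesize -> estimate -> rank.

A run is fully reproducible from (config, seed): the config records dataset
paths and the gene-to-node map, the normalization and binarization choices,
the assignment-probability set, the Beta priors, the utility table and the
candidate nodes; the seed drives every random draw through named
sub-streams.  Each stage writes a CSV another stage can consume, so stages
can be rerun in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation, preprocessing, synthesis
from .decision import (
    UtilityTable,
    per_node_maximum,
    rank_interventions,
    report,
    wrky_utility_table,
    example_utility_table,
)
from .network import (
    BinaryDataset,
    NetworkStructure,
    ParameterSet,
    build_example_network,
    build_wrky_network,
    wrky_reference_parameters,
)

__all__ = ["PipelineConfig", "run_pipeline", "run_worked_example"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    datasets: list[dict] = field(default_factory=list)  # {path, format, node_map}
    normalization: str = "zscore"
    binarization: str = "mean"
    assignment_probabilities: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0)
    prior: tuple[float, float] = (1.0, 1.0)
    utility: UtilityTable | None = None
    candidates: list[str] = field(default_factory=lambda: list("ABCDEFG"))
    seed: int = 0
    out_dir: str = "wrkybn_run"
    simulate_n: int | None = None  # if set, generate a synthetic composite instead
    demo_params: str | None = None  # CSV of injected parameters, bypassing estimation
    charts: bool = False

    def validate(self) -> None:
        if self.utility is None:
            raise ValueError("pipeline config requires a utility table")
        if not self.datasets and self.simulate_n is None and self.demo_params is None:
            raise ValueError(
                "config needs expression datasets, simulate_n, or demo_params"
            )
        for c in self.candidates:
            if self.utility.target is not None and c == self.utility.target:
                raise ValueError(f"candidate {c} is the utility target")
        synthesis.AssignmentProbabilitySet(tuple(self.assignment_probabilities))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "datasets": self.datasets,
            "normalization": self.normalization,
            "binarization": self.binarization,
            "assignment_probabilities": list(self.assignment_probabilities),
            "prior": list(self.prior),
            "utility": self.utility.to_dict() if self.utility else None,
            "candidates": list(self.candidates),
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "simulate_n": self.simulate_n,
            "demo_params": self.demo_params,
            "charts": self.charts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(
            datasets=d.get("datasets", []),
            normalization=d.get("normalization", "zscore"),
            binarization=d.get("binarization", "mean"),
            assignment_probabilities=tuple(
                d.get("assignment_probabilities", (0.6, 0.7, 0.8, 0.9, 1.0))
            ),
            prior=tuple(d.get("prior", (1.0, 1.0))),
            utility=UtilityTable.from_dict(d["utility"]) if d.get("utility") else None,
            candidates=list(d.get("candidates", list("ABCDEFG"))),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "wrkybn_run"),
            simulate_n=d.get("simulate_n"),
            demo_params=d.get("demo_params"),
            charts=bool(d.get("charts", False)),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_params_csv(path, net: NetworkStructure) -> ParameterSet:
    """Read an injected parameter table (entry,theta columns or the
    two-method layout; the Bayesian column wins when both are present)."""
    df = pd.read_csv(path)
    col = None
    for cand in ("theta", "Bayesian Approach", "bayesian", "MLE Approach", "mle"):
        if cand in df.columns:
            col = cand
            break
    if col is None:
        raise ValueError(f"no parameter column found in {path}")
    label_col = "entry" if "entry" in df.columns else "Local Probabilities"
    ref = wrky_reference_parameters()
    label_to_key = {
        label: (node, cfg) for label, node, cfg in ref.entry_labels(net)
    }
    thetas: dict[str, dict[tuple[int, ...], float]] = {n: {} for n in net.node_ids}
    for _, row in df.iterrows():
        label = row[label_col]
        if label not in label_to_key:
            raise ValueError(f"unrecognized parameter row {label!r}")
        node, cfg = label_to_key[label]
        thetas[node][cfg] = float(row[col])
    # fill entries the published layout omits (the sink H) with a neutral CPT
    import itertools as it

    for node in net.node_ids:
        for cfg in it.product((0, 1), repeat=len(net.parents[node])):
            thetas[node].setdefault(cfg, 0.5)
    ps = ParameterSet(thetas=thetas, method=f"injected ({col})")
    ps.validate(net)
    return ps


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write artifacts to ``config.out_dir``.

    Artifacts: ``composite.csv`` (binary dataset with provenance), a local
    probability table for both estimators, intervention rankings under each
    parameter set, an activation/inhibition summary per node, and
    ``run_log.yaml`` with every resolved setting.  Any stage error aborts
    with the stage name.
    """
    config.validate()
    net = build_wrky_network()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": []}
    probs = synthesis.AssignmentProbabilitySet(tuple(config.assignment_probabilities))
    artifacts: dict = {}

    def stage(name):
        log["stages"].append(name)

    try:
        if config.demo_params is not None:
            stage("inject-parameters")
            bayes = _load_params_csv(config.demo_params, net)
            mle = bayes
            composite = None
        else:
            if config.simulate_n is not None:
                stage("simulate")
                truth, composite = synthesis.generate_composite(
                    net,
                    wrky_reference_parameters(),
                    config.simulate_n,
                    seed=config.seed,
                    probs=probs,
                )
            else:
                stage("preprocess")
                binarized = []
                for spec_ in config.datasets:
                    m = preprocessing.read_expression(
                        spec_["path"], format=spec_.get("format")
                    )
                    m = preprocessing.normalize(m, config.normalization)
                    binarized.append(
                        preprocessing.binarize(
                            m, config.binarization, node_map=spec_.get("node_map")
                        )
                    )
                observed = preprocessing.aggregate(binarized)
                stage("synthesize")
                composite = synthesis.synthesize_all(
                    observed, net, seed=config.seed, probs=probs
                )
            composite.to_csv(out / "composite.csv")
            artifacts["composite"] = out / "composite.csv"

            stage("estimate")
            counts = estimation.count_sufficient_stats(composite, net)
            bayes = estimation.bayesian_estimate(counts, prior=tuple(config.prior))
            mle = estimation.mle_estimate(counts)
            # undefined MLE entries fall back to the Bayesian estimate downstream
            substituted = []
            for node, cfg in sorted(mle.undefined):
                mle.thetas[node][cfg] = bayes.thetas[node][cfg]
                substituted.append(f"{node}|{cfg}")
            if substituted:
                log["mle_substituted_from_bayes"] = substituted
            ptable = estimation.format_parameter_table(net, bayes, mle)
            ptable.to_csv(out / "parameters.csv", index=False)
            artifacts["parameters"] = out / "parameters.csv"

            stage("activation-summary")
            counts_frame = pd.DataFrame(
                {
                    "node": list(composite.frame.columns),
                    "activated": [
                        int(composite.frame[c].sum()) for c in composite.frame.columns
                    ],
                    "inhibited": [
                        int((1 - composite.frame[c]).sum())
                        for c in composite.frame.columns
                    ],
                }
            )
            counts_frame.to_csv(out / "activation_summary.csv", index=False)
            artifacts["activation_summary"] = out / "activation_summary.csv"

        stage("rank")
        rankings = {}
        for name, ps in (("bayes", bayes), ("mle", mle)):
            results = rank_interventions(net, ps, config.candidates, config.utility)
            chart = out / f"ranking_{name}.svg" if config.charts else None
            report(
                results,
                csv_path=out / f"ranking_{name}.csv",
                text_path=out / f"ranking_{name}.txt",
                chart_path=chart,
            )
            per_node_maximum(results).to_csv(
                out / f"max_utility_{name}.csv", index=False
            )
            rankings[name] = results
            artifacts[f"ranking_{name}"] = out / f"ranking_{name}.csv"

        log["best_intervention"] = {
            name: str(rankings[name][0].intervention) for name in rankings
        }
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(_jsonable(log), fh, sort_keys=False)
        artifacts["run_log"] = out / "run_log.yaml"
        artifacts["rankings"] = rankings
        artifacts["bayes"] = bayes
        artifacts["mle"] = mle
        return artifacts
    except Exception as exc:  # annotate with the failing stage
        current = log["stages"][-1] if log["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def run_worked_example(verbose: bool = False) -> dict:
    """The three-gene illustrative analysis, fully deterministic.

    Builds the example network (P(A=1)=0.7, P(B=1)=0.2), scores both
    actions at genes A and B against the example utility table, and
    recommends the maximizing action.  Returns the four expected utilities
    and the recommendation.
    """
    net, params = build_example_network()
    u = example_utility_table()
    results = rank_interventions(net, params, ["A", "B"], u)
    eus = {
        f"{r.intervention.node}={r.intervention.value}": r.expected_utility
        for r in results
    }
    best = results[0].intervention
    summary = {
        "expected_utilities": eus,
        "recommendation": f"{best.action} gene {best.node}",
        "best": {"node": best.node, "value": best.value,
                 "expected_utility": results[0].expected_utility},
    }
    if verbose:
        for r in results:
            print(
                f"EU({r.intervention.node}={r.intervention.value}) = "
                f"{r.expected_utility:g}"
            )
        print(f"decision: {summary['recommendation']}")
    return summary
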