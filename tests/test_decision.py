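"""Interventions, expected utility and ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkybn import (
    Intervention,
    build_example_network,
    example_utility_table,
    expected_utility,
    intervene,
    marginal,
    per_node_maximum,
    rank_interventions,
    report,
    table7_bayesian_parameters,
    wrky_utility_table,
)
from wrkybn.decision import UtilityTable

from conftest import as_plain, oracle_expected_utility, random_parameter_set


@pytest.fixture
def example():
    net, params = build_example_network()
    return net, params, example_utility_table()


class TestIntervene:
    def test_root_do_is_point_mass(self, example):
        net, params, _ = example
        mnet, mparams = intervene(net, params, Intervention("A", 1))
        assert mparams.thetas["A"][()] == 1.0
        assert mparams.thetas["B"][()] == 0.2  # other conditionals untouched
        assert mnet.parents["A"] == ()

    def test_root_do_equals_conditioning(self, wrky_net, ref_params):
        mnet, mparams = intervene(wrky_net, ref_params, Intervention("A", 1))
        for node in "CDH":
            p_do = marginal(mnet, mparams, {node: 1})
            p_cond = marginal(wrky_net, ref_params, {node: 1}, {"A": 1})
            assert p_do == pytest.approx(p_cond, abs=1e-12)

    def test_nonroot_do_severs_parents(self, wrky_net, ref_params):
        mnet, mparams = intervene(wrky_net, ref_params, Intervention("F", 1))
        assert mnet.parents["F"] == ()
        # upstream C keeps its distribution; downstream G sees F=1 only
        assert marginal(mnet, mparams, {"C": 1}) == pytest.approx(
            marginal(wrky_net, ref_params, {"C": 1}), abs=1e-12
        )
        assert marginal(mnet, mparams, {"G": 1}) == pytest.approx(
            ref_params.thetas["G"][(1,)], abs=1e-12
        )

    def test_target_protected(self, wrky_net, ref_params):
        u = wrky_utility_table()
        with pytest.raises(ValueError, match="utility target"):
            expected_utility(wrky_net, ref_params, Intervention("H", 1), u)


class TestExpectedUtility:
    def test_worked_example_values(self, example):
        net, params, u = example
        eus = {
            (n, v): expected_utility(net, params, Intervention(n, v), u).expected_utility
            for n, v in [("A", 1), ("A", 0), ("B", 1), ("B", 0)]
        }
        assert eus[("A", 1)] == pytest.approx(90.0)
        assert eus[("A", 0)] == pytest.approx(40.0)
        assert eus[("B", 1)] == pytest.approx(35.0)
        assert eus[("B", 0)] == pytest.approx(85.0)

    def test_outcome_distribution_normalized(self, wrky_net, ref_params):
        u = wrky_utility_table()
        for node in "ABCDEFG":
            for v in (0, 1):
                r = expected_utility(wrky_net, ref_params, Intervention(node, v), u)
                assert sum(r.outcome_distribution.values()) == pytest.approx(
                    1.0, abs=1e-12
                )
                assert u.min_utility <= r.expected_utility <= u.max_utility

    def test_clamped_scope_node_restricts_outcomes(self, wrky_net, ref_params):
        u = wrky_utility_table()
        r = expected_utility(wrky_net, ref_params, Intervention("E", 1), u)
        # scope is (G, D, E); all mass on outcomes with E=1
        for cfg, p in r.outcome_distribution.items():
            if cfg[2] == 0:
                assert p == 0.0

    def test_constant_utility(self, wrky_net, ref_params):
        u = UtilityTable(
            scope=("G", "D", "E"),
            entries={c: 7.5 for c in itertools.product((0, 1), repeat=3)},
            target="H",
        )
        for node in "ABCDEFG":
            r = expected_utility(wrky_net, ref_params, Intervention(node, 1), u)
            assert r.expected_utility == pytest.approx(7.5)

    def test_affine_shift_equivariance(self, wrky_net, ref_params):
        u = wrky_utility_table()
        r0 = expected_utility(wrky_net, ref_params, Intervention("A", 1), u)
        r1 = expected_utility(wrky_net, ref_params, Intervention("A", 1), u.shifted(13.0))
        assert r1.expected_utility == pytest.approx(r0.expected_utility + 13.0)

    def test_matches_bruteforce_oracle_all_interventions(self, wrky_net):
        rng = np.random.default_rng(17)
        ps = random_parameter_set(wrky_net, rng)
        parents, thetas = as_plain(wrky_net, ps)
        u = wrky_utility_table()
        for node in "ABCDEFG":
            for v in (0, 1):
                r = expected_utility(wrky_net, ps, Intervention(node, v), u)
                expected = oracle_expected_utility(
                    parents, thetas, node, v, u.scope, u.entries
                )
                assert r.expected_utility == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(-50, 50))
    def test_monotone_in_single_utility(self, wrky_net, seed, c):
        # raising one configuration's utility never lowers any EU
        ps = random_parameter_set(wrky_net, np.random.default_rng(seed))
        u = wrky_utility_table()
        bumped = UtilityTable(
            scope=u.scope,
            entries={**u.entries, (1, 1, 0): u.entries[(1, 1, 0)] + abs(c)},
            target="H",
        )
        for node in ("A", "E"):
            for v in (0, 1):
                lo = expected_utility(wrky_net, ps, Intervention(node, v), u)
                hi = expected_utility(wrky_net, ps, Intervention(node, v), bumped)
                assert hi.expected_utility >= lo.expected_utility - 1e-12


class TestRanking:
    def test_example_ranking(self, example):
        net, params, u = example
        results = rank_interventions(net, params, ["A", "B"], u)
        order = [(r.intervention.node, r.intervention.value) for r in results]
        assert order == [("A", 1), ("B", 0), ("A", 0), ("B", 1)]
        # activating gene A beats inhibiting gene B
        assert results[0].expected_utility > results[1].expected_utility

    def test_wrky_qualitative_ordering(self, wrky_net):
        ps = table7_bayesian_parameters()
        results = rank_interventions(wrky_net, ps, list("ABCDEFG"), wrky_utility_table())
        best = results[0].intervention
        assert (best.node, best.value) == ("A", 1)
        activations = [r for r in results if r.intervention.value == 1]
        assert activations[1].intervention.node == "G"
        eu = {
            (r.intervention.node, r.intervention.value): r.expected_utility
            for r in results
        }
        assert eu[("B", 0)] > eu[("B", 1)]
        assert eu[("E", 0)] > eu[("E", 1)]

    def test_symmetric_nodes_tie_break(self):
        from wrkybn.network import NetworkStructure, NodeSpec, ParameterSet

        net = NetworkStructure(
            nodes=(NodeSpec("A"), NodeSpec("B"), NodeSpec("C")),
            parents={"A": (), "B": (), "C": ("A", "B")},
        )
        params = ParameterSet(
            thetas={
                "A": {(): 0.5},
                "B": {(): 0.5},
                "C": {(0, 0): 0.2, (0, 1): 0.4, (1, 0): 0.4, (1, 1): 0.8},
            }
        )
        u = UtilityTable(
            scope=("A", "B"),
            entries={(1, 1): 10.0, (1, 0): 5.0, (0, 1): 5.0, (0, 0): 0.0},
            target="C",
        )
        results = rank_interventions(net, params, ["A", "B"], u)
        eus = [r.expected_utility for r in results]
        assert eus[0] == eus[1] and eus[2] == eus[3]
        # deterministic tie-break by (node, action)
        order = [(r.intervention.node, r.intervention.value) for r in results]
        assert order == [("A", 1), ("B", 1), ("A", 0), ("B", 0)]

    def test_empty_candidates_rejected(self, wrky_net, ref_params):
        with pytest.raises(ValueError):
            rank_interventions(wrky_net, ref_params, [], wrky_utility_table())


class TestReport:
    def test_empty_results(self, tmp_path):
        table = report([], csv_path=tmp_path / "r.csv", text_path=tmp_path / "r.txt")
        assert len(table) == 0
        assert (tmp_path / "r.csv").exists()

    def test_worked_example_table(self, example, tmp_path):
        net, params, u = example
        results = rank_interventions(net, params, ["A", "B"], u)
        table = report(results, csv_path=tmp_path / "r.csv")
        assert len(table) == 4
        assert sorted(table["expected_utility"]) == [35.0, 40.0, 85.0, 90.0]

    def test_csv_and_text_agree(self, example, tmp_path):
        import pandas as pd

        net, params, u = example
        results = rank_interventions(net, params, ["A", "B"], u)
        report(results, csv_path=tmp_path / "r.csv", text_path=tmp_path / "r.txt")
        csv_vals = pd.read_csv(tmp_path / "r.csv")["expected_utility"].tolist()
        text = (tmp_path / "r.txt").read_text()
        assert all(f"{v:g}" in text or f"{v}" in text for v in csv_vals)

    def test_per_node_maximum(self, example):
        net, params, u = example
        results = rank_interventions(net, params, ["A", "B"], u)
        maxima = per_node_maximum(results)
        row_a = maxima.set_index("node").loc["A"]
        assert row_a["max_expected_utility"] == 90.0
        assert row_a["best_action"] == "activate"

    def test_chart_export(self, example, tmp_path):
        net, params, u = example
        results = rank_interventions(net, params, ["A", "B"], u)
        report(results, chart_path=tmp_path / "bars.svg")
        assert (tmp_path / "bars.svg").stat().st_size > 0
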