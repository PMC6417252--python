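"""Structure, exact joint/marginal computation and forward sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkybn import (
    build_example_network,
    build_wrky_network,
    forward_sample,
    joint_probability,
    marginal,
    validate_structure,
)
from wrkybn.network import (
    NetworkStructure,
    NodeSpec,
    ParameterSet,
    ZeroEvidenceError,
    joint_table,
)

from conftest import as_plain, oracle_marginal, random_parameter_set


class TestWrkyStructure:
    def test_parent_sets_match_pathway(self, wrky_net):
        assert wrky_net.parents == {
            "A": (),
            "B": (),
            "C": ("A", "B"),
            "D": ("A",),
            "E": ("B",),
            "F": ("C",),
            "G": ("F",),
            "H": ("D", "E", "G"),
        }

    def test_complex_and_gene_roles(self, wrky_net):
        complexes = {n.id for n in wrky_net.nodes if n.is_complex}
        assert complexes == {"C", "D", "E", "G"}
        assert len(wrky_net.nodes) == 8

    def test_topological_order_exists(self, wrky_net):
        order = wrky_net.topological_order()
        pos = {n: i for i, n in enumerate(order)}
        for child, pas in wrky_net.parents.items():
            assert all(pos[p] < pos[child] for p in pas)

    def test_labels_overridable(self):
        net = build_wrky_network(labels={"A": "myTF"})
        assert net.spec("A").label == "myTF"
        assert net.spec("B").label == "WRKY40"

    def test_yaml_round_trip(self, wrky_net, tmp_path):
        p = tmp_path / "net.yaml"
        wrky_net.to_yaml(p)
        back = NetworkStructure.from_yaml(p)
        assert back.parents == wrky_net.parents
        assert {n.id: n.is_complex for n in back.nodes} == {
            n.id: n.is_complex for n in wrky_net.nodes
        }


class TestValidation:
    def test_wrky_is_valid(self, wrky_net):
        rep = validate_structure(wrky_net)
        assert rep.valid and rep.weakly_connected and not rep.warnings

    def test_cycle_rejected_at_construction(self):
        with pytest.raises(ValueError, match="cycle"):
            NetworkStructure(
                nodes=(NodeSpec("A"), NodeSpec("B")),
                parents={"A": ("B",), "B": ("A",)},
            )

    def test_isolated_node_warned(self, wrky_net):
        net = NetworkStructure(
            nodes=wrky_net.nodes + (NodeSpec("Z", "stray"),),
            parents=dict(wrky_net.parents),
        )
        rep = validate_structure(net)
        assert rep.isolated_nodes == ["Z"]
        assert any("Z" in w for w in rep.warnings)


class TestJoint:
    def test_uniform_cpts_give_1_over_256(self, wrky_net):
        ps = ParameterSet(
            thetas={
                n: {
                    cfg: 0.5
                    for cfg in itertools.product((0, 1), repeat=len(wrky_net.parents[n]))
                }
                for n in wrky_net.node_ids
            }
        )
        a = {n: 1 for n in wrky_net.node_ids}
        assert joint_probability(wrky_net, ps, a) == pytest.approx(1 / 256)

    def test_zero_theta_annihilates(self, wrky_net, ref_params):
        ps = ParameterSet(thetas={n: dict(c) for n, c in ref_params.thetas.items()})
        ps.thetas["A"][()] = 0.0
        a = {n: 1 for n in wrky_net.node_ids}
        assert joint_probability(wrky_net, ps, a) == 0.0

    def test_partial_assignment_rejected(self, wrky_net, ref_params):
        with pytest.raises(ValueError, match="incomplete"):
            joint_probability(wrky_net, ref_params, {"A": 1})

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_joint_sums_to_one(self, wrky_net, seed):
        ps = random_parameter_set(wrky_net, np.random.default_rng(seed))
        assert joint_table(wrky_net, ps).sum() == pytest.approx(1.0, abs=1e-12)


class TestMarginal:
    def test_root_marginal_is_theta(self, wrky_net, ref_params):
        assert marginal(wrky_net, ref_params, {"A": 1}) == pytest.approx(0.5)

    def test_full_query_equals_joint(self, wrky_net, ref_params):
        a = {n: (1 if n in "ADH" else 0) for n in wrky_net.node_ids}
        assert marginal(wrky_net, ref_params, a) == pytest.approx(
            joint_probability(wrky_net, ref_params, a)
        )

    def test_example_net_root_product(self):
        # independent roots: P(A=1, B=0) = 0.7 * 0.8
        net, params = build_example_network()
        assert marginal(net, params, {"A": 1, "B": 0}) == pytest.approx(0.56)

    def test_matches_bruteforce_oracle(self, wrky_net):
        rng = np.random.default_rng(7)
        ps = random_parameter_set(wrky_net, rng)
        parents, thetas = as_plain(wrky_net, ps)
        for query, evidence in [
            ({"H": 1}, None),
            ({"H": 1}, {"A": 1}),
            ({"C": 1, "G": 0}, {"B": 0, "H": 1}),
            ({"A": 0}, {"H": 0, "E": 1}),
        ]:
            assert marginal(wrky_net, ps, query, evidence) == pytest.approx(
                oracle_marginal(parents, thetas, query, evidence), abs=1e-12
            )

    def test_zero_evidence_raises(self, wrky_net, ref_params):
        ps = ParameterSet(thetas={n: dict(c) for n, c in ref_params.thetas.items()})
        ps.thetas["A"][()] = 1.0
        with pytest.raises(ZeroEvidenceError):
            marginal(wrky_net, ps, {"H": 1}, {"A": 0})

    def test_overlapping_query_evidence_rejected(self, wrky_net, ref_params):
        with pytest.raises(ValueError, match="overlap"):
            marginal(wrky_net, ref_params, {"A": 1}, {"A": 0})


class TestForwardSample:
    def test_deterministic_root(self, wrky_net, ref_params):
        ps = ParameterSet(thetas={n: dict(c) for n, c in ref_params.thetas.items()})
        ps.thetas["A"][()] = 1.0
        ds = forward_sample(wrky_net, ps, 200, seed=1)
        assert (ds.column_values("A") == 1.0).all()

    def test_same_seed_reproduces(self, wrky_net, ref_params):
        d1 = forward_sample(wrky_net, ref_params, 500, seed=42)
        d2 = forward_sample(wrky_net, ref_params, 500, seed=42)
        assert d1.frame.equals(d2.frame)

    def test_uniform_frequencies_near_half(self, wrky_net):
        ps = ParameterSet(
            thetas={
                n: {
                    cfg: 0.5
                    for cfg in itertools.product((0, 1), repeat=len(wrky_net.parents[n]))
                }
                for n in wrky_net.node_ids
            }
        )
        ds = forward_sample(wrky_net, ps, 50_000, seed=3)
        freqs = ds.frame.mean()
        assert (freqs - 0.5).abs().max() < 0.02

    def test_conditional_frequencies_recover_thetas(self, wrky_net, ref_params):
        # empirical conditional frequencies within 3 binomial SE of each theta
        ds = forward_sample(wrky_net, ref_params, 20_000, seed=11)
        f = ds.frame
        for node in wrky_net.node_ids:
            pas = wrky_net.parents[node]
            for cfg, theta in ref_params.thetas[node].items():
                mask = np.ones(len(f), dtype=bool)
                for p, v in zip(pas, cfg):
                    mask &= f[p].to_numpy() == v
                m = mask.sum()
                if m == 0:
                    continue
                emp = f[node].to_numpy()[mask].mean()
                tol = 3 * np.sqrt(theta * (1 - theta) / m) + 1e-9
                assert abs(emp - theta) <= tol, (node, cfg)

    def test_nonpositive_n_rejected(self, wrky_net, ref_params):
        with pytest.raises(ValueError):
            forward_sample(wrky_net, ref_params, 0, seed=0)
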