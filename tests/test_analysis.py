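"""Arc strength, sensitivity derivatives, cross-validation, scenarios."""

import math

import numpy as np
import pytest

from bbnes.analysis import (
    arc_strength,
    finite_difference_derivatives,
    kfold_cv,
    scenario_compare,
    sensitivity_analysis,
)
from bbnes.core import CPT, Network, NodeSpec, infer_posterior
from bbnes.learning import LearningConfig

from conftest import full_joint_tensor, random_network


def _binary_copy_net(p_copy: float = 1.0) -> Network:
    """Uniform binary parent; child copies it with probability p_copy."""
    q = 1.0 - p_copy
    return Network(
        [NodeSpec("P", ("0", "1")), NodeSpec("C", ("0", "1"))],
        [("P", "C")],
        [
            CPT("P", (), {(): np.array([0.5, 0.5])}),
            CPT(
                "C",
                ("P",),
                {("0",): np.array([p_copy, q]), ("1",): np.array([q, p_copy])},
            ),
        ],
    )


class TestArcStrength:
    def test_independent_child_gives_zero(self):
        net = Network(
            [NodeSpec("P", ("0", "1")), NodeSpec("C", ("0", "1"))],
            [("P", "C")],
            [
                CPT("P", (), {(): np.array([0.3, 0.7])}),
                CPT(
                    "C",
                    ("P",),
                    {("0",): np.array([0.6, 0.4]), ("1",): np.array([0.6, 0.4])},
                ),
            ],
        )
        assert arc_strength(net, ("P", "C")) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_copy_gives_one_bit(self):
        assert arc_strength(_binary_copy_net(), ("P", "C")) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_mutual_information(self, seed):
        rng = np.random.default_rng(seed)
        net = Network(
            [NodeSpec("P", ("a", "b", "c")), NodeSpec("C", ("x", "y", "z"))],
            [("P", "C")],
            [
                CPT("P", (), {(): rng.dirichlet(np.ones(3))}),
                CPT(
                    "C",
                    ("P",),
                    {(s,): rng.dirichlet(np.ones(3)) for s in ("a", "b", "c")},
                ),
            ],
        )
        _, joint = full_joint_tensor(net)
        pi, pj = joint.sum(axis=1), joint.sum(axis=0)
        expected = sum(
            joint[i, j] * math.log2(joint[i, j] / (pi[i] * pj[j]))
            for i in range(3)
            for j in range(3)
            if joint[i, j] > 0
        )
        assert arc_strength(net, ("P", "C")) == pytest.approx(expected, abs=1e-10)

    def test_unknown_arc_raises(self):
        with pytest.raises(ValueError, match="not in the network"):
            arc_strength(_binary_copy_net(), ("C", "P"))


class TestSensitivity:
    def test_closed_form_two_node_derivative(self, two_node_net):
        """d P(a1|b1) / d P(b1|a1) = (0.3*0.14) / (0.3*0.8 + 0.14)^2."""
        report = sensitivity_analysis(two_node_net, "A", {"B": "b1"})
        entry = next(
            e
            for e in report.entries
            if e.node == "B" and e.parent_combo == ("a1",) and e.child_state == "b1"
        )
        expected = (0.3 * 0.14) / (0.3 * 0.8 + 0.14) ** 2
        a1 = report.target_states.index("a1")
        assert entry.derivatives[a1] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_central_finite_differences(self, seed):
        net = random_network(seed, max_nodes=5)
        target = list(net.nodes)[-1]
        report = sensitivity_analysis(net, target)
        for e in report.entries:
            if 1e-3 < e.theta < 1 - 1e-3:
                fd = finite_difference_derivatives(
                    net, target, {}, e.node, e.parent_combo,
                    net.states(e.node).index(e.child_state), h=1e-5,
                )
                np.testing.assert_allclose(e.derivatives, fd, atol=1e-6)

    def test_d_separated_parameters_are_exactly_zero(self, uniform_chain3):
        # evidence on B blocks A from C: C's parameters cannot move P(A|B)
        report = sensitivity_analysis(uniform_chain3, "A", {"B": "0"})
        for e in report.entries:
            if e.node == "C":
                assert np.all(e.derivatives == 0.0)

    def test_statewise_derivatives_sum_to_zero(self, two_node_net):
        report = sensitivity_analysis(two_node_net, "A", {"B": "b1"})
        for e in report.entries:
            assert abs(float(e.derivatives.sum())) <= 1e-8

    def test_target_in_evidence_rejected(self, two_node_net):
        with pytest.raises(ValueError, match="must not be part of the evidence"):
            sensitivity_analysis(two_node_net, "A", {"A": "a1"})

    def test_ranking_sorted_descending(self, two_node_net):
        report = sensitivity_analysis(two_node_net, "A", {"B": "b1"})
        values = [v for _, v in report.ranking]
        assert values == sorted(values, reverse=True)
        assert all(v >= 0 for v in values)


class TestKFoldCV:
    def _records(self, net, n, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            p = "0" if rng.random() < 0.5 else "1"
            col = net.cpts["C"].column((p,))
            c = net.states("C")[rng.choice(2, p=col)]
            rows.append({"P": p, "C": c})
        return rows

    def test_deterministic_copy_is_perfect(self):
        net = _binary_copy_net(1.0)
        records = self._records(net, 200, seed=0)
        result = kfold_cv(net, records, 5, "C", LearningConfig(alpha=1.0, nodes=("P", "C")), seed=1)
        assert result.fold_accuracy == [1.0] * 5

    def test_fold_arithmetic(self):
        net = _binary_copy_net(1.0)
        records = self._records(net, 10, seed=2)
        result = kfold_cv(net, records, 10, "C", LearningConfig(alpha=1.0, nodes=("P", "C")), seed=0)
        assert result.fold_sizes == [1] * 10

    def test_noisy_channel_accuracy_near_capacity(self):
        """child = parent with prob 0.9: MAP accuracy concentrates at 0.9."""
        net = _binary_copy_net(0.9)
        records = self._records(net, 5000, seed=3)
        result = kfold_cv(net, records, 5, "C", LearningConfig(alpha=1.0, nodes=("P", "C")), seed=4)
        half_width = 2.576 * math.sqrt(0.9 * 0.1 / 5000)
        assert abs(result.accuracy - 0.9) < half_width

    def test_reproducible_given_seed(self):
        net = _binary_copy_net(0.8)
        records = self._records(net, 300, seed=5)
        cfg = LearningConfig(alpha=1.0, nodes=("P", "C"))
        r1 = kfold_cv(net, records, 4, "C", cfg, seed=9)
        r2 = kfold_cv(net, records, 4, "C", cfg, seed=9)
        assert r1.fold_accuracy == r2.fold_accuracy
        assert r1.fold_logloss == r2.fold_logloss

    def test_folds_partition_with_near_equal_sizes(self):
        net = _binary_copy_net(0.8)
        records = self._records(net, 103, seed=6)
        result = kfold_cv(net, records, 5, "C", LearningConfig(alpha=1.0, nodes=("P", "C")), seed=0)
        assert sum(result.fold_sizes) == 103
        assert max(result.fold_sizes) - min(result.fold_sizes) <= 1

    def test_bad_k_rejected(self):
        net = _binary_copy_net(1.0)
        records = self._records(net, 5, seed=7)
        with pytest.raises(ValueError, match="k must be >= 2"):
            kfold_cv(net, records, 1, "C")
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(net, records, 10, "C")


class TestScenarios:
    def test_baseline_equals_prior_marginals(self, sh_learned):
        _, _, _, net = sh_learned
        table = scenario_compare(net, [], ["soil_texture", "budget"])
        prior = infer_posterior(net, "soil_texture")["soil_texture"]
        np.testing.assert_allclose(
            table.posteriors["baseline"]["soil_texture"].probabilities,
            prior.probabilities,
            atol=0,
        )

    def test_d_separated_query_unchanged_by_evidence(self, two_node_net):
        # add a disconnected node D: evidence on B cannot move it
        from bbnes.core import CPT as _CPT, Network as _Net, NodeSpec as _Spec

        net = _Net(
            list(two_node_net.nodes.values()) + [_Spec("D", ("d1", "d2"))],
            list(two_node_net.arcs),
            {**two_node_net.cpts, "D": _CPT("D", (), {(): np.array([0.25, 0.75])})},
        )
        table = scenario_compare(net, [("b1", {"B": "b1"})], ["A", "D"])
        np.testing.assert_allclose(
            table.posteriors["b1"]["D"].probabilities,
            table.posteriors["baseline"]["D"].probabilities,
            atol=1e-12,
        )

    def test_geest_raises_sand_probability(self, sh_learned):
        _, _, _, net = sh_learned
        table = scenario_compare(
            net, [("geest", {"landscape_type": "geest"})], ["soil_texture"]
        )
        sand_given_geest = table.posteriors["geest"]["soil_texture"]["sand"]
        sand_prior = table.posteriors["baseline"]["soil_texture"]["sand"]
        assert sand_given_geest > sand_prior

    def test_arc_strengths_cover_all_arcs(self, sh_learned):
        _, _, _, net = sh_learned
        table = scenario_compare(net, [], ["budget"])
        assert set(table.arc_strengths) == {tuple(a) for a in net.arcs}
        assert all(v >= 0 for v in table.arc_strengths.values())
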