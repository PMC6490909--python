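"""The 14-node model: structure, discretization, lookups, expert CPTs."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbnes.core import validate_network
from bbnes.model import (
    EXPERT_NODES,
    NODE_STATES,
    POTENTIAL_STATES,
    ESMatrixTable,
    ExpertCPTParams,
    GridRecord,
    budget_state,
    build_network,
    default_expert_cpt,
    default_scheme,
    discretize_record,
    favourability_score,
    lookup_preliminary_potential,
    quantile_breaks,
    reclassify_potential,
)


class TestStructure:
    def test_fourteen_nodes_and_valid(self):
        net = build_network()
        assert len(net.nodes) == 14
        assert validate_network(net) == []

    def test_demand_states_are_surplus_classes(self):
        net = build_network()
        assert net.states("demand") == ("low", "medium", "high")
        scheme = default_scheme()
        assert scheme.classify("nitrogen_surplus", 40.0) == "low"
        assert scheme.classify("nitrogen_surplus", 41.0) == "medium"
        assert scheme.classify("nitrogen_surplus", 61.0) == "high"

    def test_state_catalogue(self):
        net = build_network()
        for name, states in NODE_STATES.items():
            assert net.states(name) == states

    def test_custom_arcs_stay_acyclic_and_usable(self):
        arcs = [a for a in build_network().arcs]
        net = build_network(arcs=arcs)
        assert validate_network(net) == []


BOUNDARY_CASES = [
    # (variable, value, expected state) — full boundary coverage
    ("field_capacity", 0.0, "low"),
    ("field_capacity", 199.999, "low"),
    ("field_capacity", 200.0, "medium"),
    ("field_capacity", 250.0, "medium"),
    ("field_capacity", 300.0, "medium"),
    ("field_capacity", 300.001, "high"),
    ("natural_nutrient_availability", 299.0, "low"),
    ("natural_nutrient_availability", 300.0, "medium"),
    ("natural_nutrient_availability", 600.0, "medium"),
    ("natural_nutrient_availability", 601.0, "high"),
    ("nitrogen_surplus", -10.0, "low"),
    ("nitrogen_surplus", 40.0, "low"),
    ("nitrogen_surplus", 40.5, "medium"),
    ("nitrogen_surplus", 60.0, "medium"),
    ("nitrogen_surplus", 60.001, "high"),
    ("nitrogen_surplus", 70.0, "high"),
    ("slope", 0.0, "low"),
    ("slope", 0.1, "low"),
    ("slope", 0.2039, "low"),
    ("slope", 0.204, "medium"),
    ("slope", 0.6581, "medium"),
    ("slope", 0.66, "high"),
    ("slope", 13.4431, "high"),
]


class TestDiscretization:
    @pytest.mark.parametrize("variable,value,expected", BOUNDARY_CASES)
    def test_interval_classification(self, variable, value, expected):
        assert default_scheme().classify(variable, value) == expected

    def test_every_boundary_belongs_to_exactly_one_state(self):
        scheme = default_scheme()
        for var in (
            "field_capacity",
            "natural_nutrient_availability",
            "nitrogen_surplus",
            "slope",
        ):
            bands = getattr(scheme, var)
            boundaries = {b.lo for _, b in bands} | {b.hi for _, b in bands}
            for x in boundaries:
                if not math.isfinite(x):
                    continue
                hits = [lab for lab, band in bands if x in band]
                assert len(hits) == 1, (var, x, hits)

    def test_value_outside_domain_raises(self):
        with pytest.raises(ValueError, match="outside every declared interval"):
            default_scheme().classify("field_capacity", -5.0)

    def test_discretize_record_full(self):
        rec = GridRecord(
            cell_id=0,
            landscape_type="geest",
            lulc_class=312,
            slope=0.1,
            field_capacity=250.0,
            nutrient_availability=700.0,
            soil_texture="sand",
            wind_erosion="high",
            water_erosion="no",
            nitrate_leaching="high",
            nitrogen_surplus=70.0,
        )
        states = discretize_record(rec, default_scheme(), ESMatrixTable({312: 4}))
        assert states == {
            "landscape_type": "geest",
            "soil_texture": "sand",
            "slope": "low",
            "field_capacity": "medium",
            "wind_erosion": "high",
            "water_erosion": "no",
            "natural_nutrient_availability": "high",
            "nitrate_leaching_potential": "high",
            "preliminary_potential": "P_4",
            "demand": "high",
        }

    def test_negative_slope_rejected_at_record_level(self):
        with pytest.raises(ValueError, match="slope"):
            GridRecord(
                cell_id=1,
                landscape_type="geest",
                lulc_class=312,
                slope=-1.0,
                field_capacity=100.0,
                nutrient_availability=100.0,
                soil_texture="sand",
                wind_erosion="no",
                water_erosion="no",
                nitrate_leaching="low",
                nitrogen_surplus=0.0,
            )


class TestQuantileBreaks:
    def test_documented_order_statistic_rule(self):
        assert quantile_breaks(range(1, 10), 3) == (3, 6)

    def test_order_independence(self):
        assert quantile_breaks([3, 1, 4, 2], 2) == (2,)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            quantile_breaks([5.0] * 10, 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=6, max_size=40, unique=True))
    def test_breaks_are_order_statistics_regardless_of_shuffling(self, values):
        breaks = quantile_breaks(values, 3)
        assert breaks == quantile_breaks(sorted(values, reverse=True), 3)
        assert all(b in values for b in breaks)
        assert breaks[0] < breaks[1]


class TestLookupsAndMappings:
    def test_matrix_lookup(self):
        assert lookup_preliminary_potential(312, ESMatrixTable({312: 4})) == "P_4"
        assert lookup_preliminary_potential(231, ESMatrixTable({231: 0})) == "P_no"

    def test_unknown_code_raises(self):
        with pytest.raises(KeyError, match="no entry"):
            lookup_preliminary_potential(999, ESMatrixTable({312: 4}))

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0..5"):
            ESMatrixTable({100: 6})

    @pytest.mark.parametrize(
        "p,expected",
        [
            ("P_no", "low"),
            ("P_1", "low"),
            ("P_2", "medium"),
            ("P_3", "medium"),
            ("P_4", "high"),
            ("P_5", "high"),
        ],
    )
    def test_reclassification_truth_table(self, p, expected):
        assert reclassify_potential(p) == expected

    def test_reclassify_unknown_state(self):
        with pytest.raises(ValueError, match="unknown potential"):
            reclassify_potential("P_9")

    @pytest.mark.parametrize(
        "potential,demand,expected",
        [
            ("low", "low", "sustainable"),
            ("low", "medium", "unsustainable"),
            ("low", "high", "unsustainable"),
            ("medium", "low", "sustainable"),
            ("medium", "medium", "sustainable"),
            ("medium", "high", "unsustainable"),
            ("high", "low", "sustainable"),
            ("high", "medium", "sustainable"),
            ("high", "high", "sustainable"),
        ],
    )
    def test_budget_truth_table_default_tie_rule(self, potential, demand, expected):
        assert budget_state(potential, demand) == expected

    def test_budget_strict_tie_rule(self):
        assert budget_state("medium", "medium", sustainable_on_tie=False) == "unsustainable"

    def test_budget_unknown_state(self):
        with pytest.raises(ValueError, match="unknown"):
            budget_state("tiny", "low")


class TestExpertCPTs:
    @pytest.mark.parametrize("node", EXPERT_NODES)
    def test_columns_normalized(self, node):
        cpt = default_expert_cpt(node)
        for combo, col in cpt.table.items():
            assert abs(col.sum() - 1.0) <= 1e-9, (node, combo)
            assert np.all(col >= 0)

    def test_erosion_peaks_at_ordinal_max(self):
        cpt = default_expert_cpt("erosion")
        col = cpt.column(("high", "no"))
        assert int(np.argmax(col)) == 2  # "high"
        col2 = cpt.column(("no", "no"))
        assert int(np.argmax(col2)) == 0  # "low"

    def test_potential_peaks_at_former_state_with_mass_below_one(self):
        cpt = default_expert_cpt("nutrient_regulation_potential")
        # neutral favourability: medium everywhere -> score 0 -> no shift
        col = cpt.column(("medium", "medium", "medium", "medium", "P_1"))
        assert int(np.argmax(col)) == POTENTIAL_STATES.index("P_1")
        assert float(col.max()) < 1.0

    def test_potential_expected_rank_monotone_in_favourability(self):
        """Raising the favourability score never lowers the expected ordinal
        potential, for every preliminary state."""
        cpt = default_expert_cpt("nutrient_regulation_potential")
        lmh = ("low", "medium", "high")
        ranks = np.arange(6)
        for prelim in POTENTIAL_STATES:
            by_score: dict[int, set[float]] = {}
            for fc, nna, nl, er in itertools.product(lmh, repeat=4):
                s = favourability_score(fc, nna, nl, er)
                exp_rank = float(ranks @ cpt.column((fc, nna, nl, er, prelim)))
                by_score.setdefault(s, set()).add(round(exp_rank, 12))
            scores = sorted(by_score)
            maxima = [max(by_score[s]) for s in scores]
            minima = [min(by_score[s]) for s in scores]
            for lo, hi in zip(maxima, minima[1:]):
                assert lo <= hi + 1e-12

    def test_deterministic_nodes_are_point_mass(self):
        for node in ("reclassified_potential", "budget"):
            cpt = default_expert_cpt(node)
            for col in cpt.table.values():
                assert set(np.round(col, 12)) <= {0.0, 1.0}

    def test_non_expert_node_rejected(self):
        with pytest.raises(ValueError, match="not an expert node"):
            default_expert_cpt("soil_texture")

    def test_params_are_configurable(self):
        cpt = default_expert_cpt("budget", ExpertCPTParams(sustainable_on_tie=False))
        col = cpt.column(("medium", "medium"))
        assert col[1] == 1.0  # unsustainable under the strict tie rule
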