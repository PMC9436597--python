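import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copdcea.parameters import (
    ALIVE_STATES,
    Arm,
    ConfigurationError,
    ParameterValidationError,
    Phase,
    STATE_INDEX,
    State,
    initial_distribution,
    iter_parameters,
    load_fixture,
    load_parameters,
    params_to_dict,
    rescale_probability,
)


class TestRescaleProbability:
    """Constant-rate rescaling between cycle lengths."""

    @pytest.mark.parametrize(
        "p1, t1, t2, expected",
        [
            (0.0, 1.0, 0.25, 0.0),
            (0.048, 0.25, 0.25, 0.048),
            # 1 - exp(-0.25 * (-ln 0.81)) evaluated independently
            (0.19, 1.0, 0.25, 0.051316701949486156),
            (1.0, 1.0, 0.25, 1.0),
        ],
    )
    def test_known_values(self, p1, t1, t2, expected):
        assert rescale_probability(p1, t1, t2) == pytest.approx(expected, abs=1e-12)

    def test_rejects_invalid_domain(self):
        with pytest.raises(ValueError):
            rescale_probability(1.2, 1.0, 0.25)
        with pytest.raises(ValueError):
            rescale_probability(0.5, 0.0, 0.25)

    @given(
        p=st.floats(min_value=0.0, max_value=0.999),
        k=st.integers(min_value=1, max_value=12),
    )
    @settings(max_examples=100, derandomize=True)
    def test_composition_recovers_original(self, p, k):
        """Applying the per-subcycle probability k times recovers p."""
        per_cycle = rescale_probability(p, 1.0, 1.0 / k)
        recomposed = 1.0 - (1.0 - per_cycle) ** k
        assert recomposed == pytest.approx(p, abs=1e-12)

    @given(
        p_lo=st.floats(min_value=0.0, max_value=0.99),
        delta=st.floats(min_value=1e-6, max_value=0.009),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_p(self, p_lo, delta):
        assert rescale_probability(p_lo + delta, 1.0, 0.25) > rescale_probability(
            p_lo, 1.0, 0.25
        )


class TestInitialDistribution:
    def test_published_stage_counts_normalize_over_staged_patients(self):
        occ = initial_distribution({"II": 395, "III": 375, "IV": 111})
        # 395/881, 375/881, 111/881 (hand division)
        assert occ[STATE_INDEX[State.C]] == pytest.approx(0.44835, abs=1e-5)
        assert occ[STATE_INDEX[State.B]] == pytest.approx(0.42565, abs=1e-5)
        assert occ[STATE_INDEX[State.A]] == pytest.approx(0.12599, abs=1e-5)
        assert occ[STATE_INDEX[State.DEATH]] == 0.0

    def test_single_stage_cohort(self):
        occ = initial_distribution((100, 0, 0))
        assert occ[STATE_INDEX[State.C]] == 1.0
        assert occ.sum() == 1.0

    def test_normalization_identity(self):
        occ = initial_distribution({"II": 389, "III": 376, "IV": 106})
        assert abs(occ.sum() - 1.0) < 1e-12

    def test_positional_mapping_reverses_stage_assignment(self):
        sev = initial_distribution((10, 20, 70), "severity")
        pos = initial_distribution((10, 20, 70), "positional")
        assert sev[STATE_INDEX[State.C]] == pos[STATE_INDEX[State.A]]
        assert sev[STATE_INDEX[State.B]] == pos[STATE_INDEX[State.B]]

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            initial_distribution((0, 0, 0))


class TestFixtureLoading:
    def test_published_point_probabilities(self, fixture_params):
        t = fixture_params.transitions[(Arm.UMEC_VI, Phase.BASE)]
        a = STATE_INDEX[State.A]
        assert t.probs[a, a] == 0.952
        assert t.probs[a, STATE_INDEX[State.DEATH]] == 0.048
        t_tio = fixture_params.transitions[(Arm.TIO, Phase.NEW)]
        c = STATE_INDEX[State.C]
        assert t_tio.probs[c, STATE_INDEX[State.B]] == 0.026

    def test_rows_sum_to_one(self, fixture_params):
        for table in fixture_params.transitions.values():
            np.testing.assert_allclose(table.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_dirichlet_counts_reproduce_probabilities(self, fixture_params):
        """counts/total matches each printed probability to <= 1e-3."""
        for table in fixture_params.transitions.values():
            for s in ALIVE_STATES:
                i = STATE_INDEX[s]
                total = table.counts[i].sum()
                np.testing.assert_allclose(
                    table.counts[i] / total, table.probs[i], atol=1e-3
                )

    def test_beta_means_reproduce_utilities(self, fixture_params):
        for s, bp in fixture_params.utilities.annual.items():
            assert bp.alpha / (bp.alpha + bp.beta) == pytest.approx(
                bp.point, abs=5e-4
            )

    def test_gamma_means_reproduce_ae_probabilities(self, fixture_params):
        for arm, events in fixture_params.adverse_events.per_cycle.items():
            for event, gp in events.items():
                assert gp.shape * gp.scale == pytest.approx(gp.point, abs=5e-4)

    def test_unpriced_probability_free_ae_flagged_inactive(self, fixture_params):
        assert fixture_params.adverse_events.inactive == ("oropharyngeal_pain",)

    def test_wtp_is_three_times_gdp(self, fixture_params):
        assert fixture_params.wtp_per_qaly == 3 * fixture_params.gdp_per_capita
        assert fixture_params.wtp_per_qaly == 31554.0

    def test_unknown_fixture_name(self):
        with pytest.raises(ConfigurationError):
            load_fixture("no-such-model")


class TestLoadValidation:
    def test_round_trip_identity(self, fixture_params):
        doc = params_to_dict(fixture_params)
        reloaded = load_parameters(doc)
        assert params_to_dict(reloaded) == doc

    def test_missing_section_names_it(self, fixture_params):
        doc = params_to_dict(fixture_params)
        doc.pop("utilities")
        with pytest.raises(ConfigurationError, match="utilities"):
            load_parameters(doc)

    def test_rescaled_row_names_offending_row(self, fixture_params):
        doc = params_to_dict(fixture_params)
        row = doc["transitions"]["TIO"]["BASE"]["B"]
        for dst in row:
            row[dst][0] *= 0.9
        with pytest.raises(ParameterValidationError, match="TIO/BASE B"):
            load_parameters(doc)

    def test_negative_cost_rejected(self, fixture_params):
        doc = params_to_dict(fixture_params)
        doc["costs"]["drug"]["TIO"] = [-1.0, -1.2, -0.8]
        with pytest.raises(ParameterValidationError, match="drug"):
            load_parameters(doc)

    def test_validation_reports_all_problems_at_once(self, fixture_params):
        doc = params_to_dict(fixture_params)
        doc["costs"]["drug"]["TIO"] = [-1.0, -1.2, -0.8]
        doc["utilities"]["B"] = [0.95, 160.56, 62.44]  # breaks mean and order
        with pytest.raises(ParameterValidationError) as err:
            load_parameters(doc)
        assert len(err.value.problems) >= 2

    def test_swapped_drug_costs_load_but_change_totals(self, fixture_params):
        from copdcea.markov import evaluate_arm

        doc = params_to_dict(fixture_params)
        doc["costs"]["drug"]["UMEC_VI"], doc["costs"]["drug"]["TIO"] = (
            doc["costs"]["drug"]["TIO"],
            doc["costs"]["drug"]["UMEC_VI"],
        )
        swapped = load_parameters(doc)
        orig = evaluate_arm(fixture_params, Arm.UMEC_VI).total_cost
        assert evaluate_arm(swapped, Arm.UMEC_VI).total_cost > orig


class TestParameterRegistry:
    def test_enumeration_is_deterministic(self, fixture_params):
        ids = [h.id for h in iter_parameters(fixture_params)]
        assert ids == [h.id for h in iter_parameters(fixture_params)]
        assert len(ids) == len(set(ids))

    def test_inactive_ae_cost_not_enumerated(self, fixture_params):
        ids = [h.id for h in iter_parameters(fixture_params)]
        assert "cost.adverse_event[oropharyngeal_pain]" not in ids

    def test_transition_setter_keeps_row_stochastic(self, fixture_params):
        params = fixture_params.copy()
        handle = next(
            h for h in iter_parameters(params) if h.kind == "dirichlet"
        )
        handle.set(params, 0.5)
        arm, phase = Arm.UMEC_VI, Phase.BASE
        # every row in every table still sums to one
        for table in params.transitions.values():
            np.testing.assert_allclose(table.probs.sum(axis=1), 1.0, atol=1e-12)
        assert handle.get(params) == 0.5

    def test_structural_zeros_survive_perturbation(self, fixture_params):
        params = fixture_params.copy()
        for handle in iter_parameters(params):
            if handle.kind == "dirichlet":
                handle.set(params, min(1.0, handle.point * 1.5))
        for table in params.transitions.values():
            assert np.all(table.probs[table.counts == 0][:-1] >= 0)
            # zero-count destinations in multi-destination rows stay zero
            for s in ALIVE_STATES:
                i = STATE_INDEX[s]
                if (table.counts[i] > 0).sum() > 1:
                    assert np.all(table.probs[i][table.counts[i] == 0] == 0)
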