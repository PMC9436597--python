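import numpy as np
import pytest

from copdcea.markov import Arm
from copdcea.owsa import base_case
from copdcea.parameters import ALIVE_STATES, Phase
from copdcea.psa import (
    DistributionSpec,
    PSASampleSet,
    ceac,
    default_wtp_grid,
    draw_parameter_set,
    prob_cost_effective,
    run_psa,
    scatter_frame,
)


class TestDistributionSpec:
    @pytest.mark.parametrize(
        "kind, params",
        [
            ("beta", (310.8375, 72.9125)),
            ("gamma", (21.6629, 0.0007)),
            ("uniform", (0.8, 1.2)),
            ("dirichlet_row", (1223.0, 39.0, 0.0, 34.0)),
            ("fixed", ()),
        ],
    )
    def test_valid_specs_construct(self, kind, params):
        DistributionSpec(kind, params)

    @pytest.mark.parametrize(
        "kind, params",
        [
            ("beta", (0.0, 1.0)),
            ("gamma", (1.0, -0.1)),
            ("uniform", (2.0, 1.0)),
            ("dirichlet_row", (0.0, 0.0)),
            ("lognormal", (0.0, 1.0)),
        ],
    )
    def test_invalid_specs_fail_at_construction(self, kind, params):
        with pytest.raises(ValueError):
            DistributionSpec(kind, params)


class TestDrawParameterSet:
    def test_sampled_rows_stay_stochastic_with_structural_zeros(
        self, fixture_params
    ):
        rng = np.random.default_rng(7)
        for _ in range(200):
            sampled = draw_parameter_set(fixture_params, rng)
            for arm, p in sampled.items():
                for phase in Phase:
                    table = p.transitions[(arm, phase)]
                    np.testing.assert_allclose(
                        table.probs.sum(axis=1), 1.0, atol=1e-12
                    )
                    assert np.all(table.probs[table.counts == 0][:-1] == 0)

    def test_beta_utility_sample_mean(self, fixture_params):
        """Mean of 10,000 draws of beta(160.56, 62.44) is 0.720 +/- 0.006."""
        rng = np.random.default_rng(11)
        b = fixture_params.utilities.annual[ALIVE_STATES[1]]
        assert (b.alpha, b.beta) == (160.56, 62.44)
        draws = rng.beta(b.alpha, b.beta, size=10_000)
        assert draws.mean() == pytest.approx(0.720, abs=0.006)

    def test_shared_mode_shares_state_block(self, fixture_params):
        params = fixture_params.copy()
        params.conventions.psa_shared_params = True
        sampled = draw_parameter_set(params, np.random.default_rng(3))
        assert sampled[Arm.UMEC_VI] is sampled[Arm.TIO]

    def test_arm_specific_mode_draws_independent_blocks(self, fixture_params):
        sampled = draw_parameter_set(fixture_params, np.random.default_rng(3))
        u1 = sampled[Arm.UMEC_VI].utilities.annual[ALIVE_STATES[0]].point
        u2 = sampled[Arm.TIO].utilities.annual[ALIVE_STATES[0]].point
        assert u1 != u2


class TestRunPsa:
    def test_empty_run(self, fixture_params):
        samples = run_psa(fixture_params, n_draws=0, seed=1)
        assert samples.n_draws == 0
        with pytest.raises(ValueError):
            prob_cost_effective(samples, 31554.0)

    def test_seed_determinism(self, fixture_params):
        a = run_psa(fixture_params, n_draws=40, seed=123)
        b = run_psa(fixture_params, n_draws=40, seed=123)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)
        c = run_psa(fixture_params, n_draws=40, seed=124)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_degenerate_psa_equals_base_case(self, fixture_params):
        """With all counts/bounds collapsed to the point values, every draw
        reproduces the deterministic base case exactly."""
        params = fixture_params.copy()
        for table in params.transitions.values():
            table.counts[:] = 0.0  # single-support rows: sampling is a no-op
        for block in (
            list(params.costs.drug.values())
            + list(params.costs.management.values())
            + list(params.costs.adverse_event.values())
            + list(params.costs.exacerbation.values())
            + list(params.exacerbations.severe.values())
            + list(params.exacerbations.nonsevere.values())
        ):
            block.low = block.high = block.point
        # beta/gamma have no exactly-degenerate form; enormous concentration
        # collapses them onto the point far below the assertion tolerance
        for s, bp in params.utilities.annual.items():
            bp.alpha, bp.beta = bp.point * 1e12, (1 - bp.point) * 1e12
        for arm_events in params.adverse_events.per_cycle.values():
            for gp in arm_events.values():
                gp.shape, gp.scale = 1e12, gp.point / 1e12
        base = base_case(params)
        samples = run_psa(params, n_draws=8, seed=5)
        np.testing.assert_allclose(samples.delta_cost, base.delta_cost, atol=1e-4)
        np.testing.assert_allclose(samples.delta_qaly, base.delta_qaly, atol=1e-5)

    def test_mean_delta_cost_near_base_case(self, fixture_params):
        """Distributions are centred on the point values, so the PSA mean
        should sit within 3 Monte-Carlo SEs of the deterministic delta."""
        samples = run_psa(fixture_params, n_draws=400, seed=17)
        base = base_case(fixture_params)
        se = samples.delta_cost.std(ddof=1) / np.sqrt(samples.n_draws)
        assert abs(samples.delta_cost.mean() - base.delta_cost) < 3 * se

    def test_gamma_truncation_is_negligible_for_fixture(self, fixture_params):
        samples = run_psa(fixture_params, n_draws=200, seed=2)
        assert samples.gamma_truncated_fraction < 1e-6


class TestCeSummaries:
    def _samples(self, d_cost, d_qaly):
        d_cost, d_qaly = np.asarray(d_cost, float), np.asarray(d_qaly, float)
        return PSASampleSet(
            seed=0,
            n_draws=len(d_cost),
            delta_cost=d_cost,
            delta_qaly=d_qaly,
            shared_params=False,
            wtp_per_qaly=31554.0,
        )

    def test_prob_cost_effective_hand_example(self):
        """NMBs at wtp=100 are +20, 0, -20; the tie counts as cost-effective."""
        s = self._samples([-10.0, 10.0, 10.0], [0.1, 0.1, -0.1])
        assert prob_cost_effective(s, 100.0) == pytest.approx(2.0 / 3.0)

    def test_dominant_cloud_is_always_cost_effective(self):
        s = self._samples([-5.0, -1.0], [0.1, 0.2])
        for wtp in (0.0, 100.0, 31554.0):
            assert prob_cost_effective(s, wtp) == 1.0

    def test_ceac_at_zero_wtp_counts_cost_savings(self, fixture_params):
        samples = run_psa(fixture_params, n_draws=120, seed=3)
        curve = ceac(samples, [0.0, 31554.0])
        assert curve["p_cost_effective_UMEC_VI"].iloc[0] == pytest.approx(
            (samples.delta_cost <= 0).mean()
        )

    def test_ceac_probabilities_complementary(self, fixture_params):
        samples = run_psa(fixture_params, n_draws=60, seed=9)
        curve = ceac(samples, default_wtp_grid(31554.0))
        total = (
            curve["p_cost_effective_UMEC_VI"] + curve["p_cost_effective_TIO"]
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        assert (curve["wtp"].diff().dropna() > 0).all()

    def test_default_grid_includes_threshold(self):
        grid = default_wtp_grid(31554.0)
        assert 31554.0 in grid
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(3 * 31554.0)

    def test_scatter_frame_schema(self, fixture_params):
        samples = run_psa(fixture_params, n_draws=5, seed=1)
        frame = scatter_frame(samples)
        assert list(frame.columns) == ["draw", "delta_cost", "delta_qaly"]
        assert len(frame) == 5

    def test_monte_carlo_se_shrinks_with_sqrt_n(self, fixture_params):
        """Quadrupling the draw count roughly halves the seed-to-seed SD of
        the probability-cost-effective estimate."""
        wtp = fixture_params.wtp_per_qaly
        p_small = [
            prob_cost_effective(run_psa(fixture_params, 50, seed), wtp)
            for seed in range(10)
        ]
        p_large = [
            prob_cost_effective(run_psa(fixture_params, 200, seed + 100), wtp)
            for seed in range(10)
        ]
        ratio = np.std(p_small, ddof=1) / np.std(p_large, ddof=1)
        assert 1.0 < ratio < 4.0
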