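"""Global fitting, model selection, constrained and efficiency-only fits."""

import numpy as np
import pytest

from nqokinetics import (
    RateGrid,
    RateLawParams,
    SaturationError,
    catalytic_efficiency,
    efficiency_from_constants,
    fit_cosubstrate_constrained,
    fit_efficiency_only,
    fit_global_pingpong,
    pingpong_rate,
    select_inhibition_model,
)
from nqokinetics import simulate as sim

from conftest import replicate_seeds


def noise_free_grid(truth, a_levels, b_levels, replicates=3, **kw):
    scn = sim.KineticScenario(
        truth, a_levels, b_levels, replicates=replicates, prop_sd=0.0, seed=0, **kw
    )
    return sim.simulate_rate_grid(scn)


class TestGlobalFit:
    def test_noise_free_round_trip_recovers_truth(self, human_truth):
        grid = noise_free_grid(human_truth, sim.BNAH_LEVELS, sim.MENADIONE_LEVELS)
        res = fit_global_pingpong(grid)
        assert res.converged
        assert res.params.kcat == pytest.approx(human_truth.kcat, rel=1e-6)
        assert res.params.K_A == pytest.approx(human_truth.K_A, rel=1e-6)
        assert res.params.K_B == pytest.approx(human_truth.K_B, rel=1e-6)

    def test_noise_free_round_trip_with_inhibition(self, duck_truth):
        grid = noise_free_grid(duck_truth, sim.BNAH_LEVELS, sim.MENADIONE_DENSE)
        res = fit_global_pingpong(grid, with_inhibition=True)
        for name in ("kcat", "K_A", "K_B", "K_I"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(duck_truth, name), rel=1e-6
            )

    def test_rate_doubling_doubles_kcat_only(self, human_truth):
        grid = noise_free_grid(human_truth, sim.BNAH_LEVELS, sim.MENADIONE_LEVELS)
        doubled = RateGrid(
            grid.a, grid.b, 2.0 * grid.rate, grid.replicate, grid.enzyme_nM
        )
        r1 = fit_global_pingpong(grid)
        r2 = fit_global_pingpong(doubled)
        assert r2.params.kcat == pytest.approx(2 * r1.params.kcat, rel=1e-6)
        assert r2.params.K_A == pytest.approx(r1.params.K_A, rel=1e-6)
        assert r2.params.K_B == pytest.approx(r1.params.K_B, rel=1e-6)

    def test_ci_brackets_estimate_and_efficiency_is_exact_quotient(self, human_truth):
        grid = sim.simulate_rate_grid(sim.human_bnah_scenario(seed=11))
        res = fit_global_pingpong(grid)
        for name, (lo, hi) in res.conf_int().items():
            est = getattr(res.params, name)
            assert lo < est < hi
        assert res.efficiency.value == pytest.approx(
            efficiency_from_constants(res.params.kcat, res.params.K_A), rel=1e-12
        )

    def test_degenerate_grid_rejected(self, human_truth):
        with pytest.raises(ValueError):
            grid = RateGrid(
                a=np.full(6, 10.0),
                b=np.tile([5.0, 20.0, 80.0], 2),
                rate=np.ones(6),
                replicate=np.arange(6),
                enzyme_nM=1.0,
            )
            fit_global_pingpong(grid)

    def test_brute_force_lattice_agrees_with_optimizer(self):
        # 2 free parameters (kcat, K_A) on a small grid, frozen acceptor
        # constants: a dense log-lattice RSS search is the independent oracle
        truth = RateLawParams(kcat=50.0, K_A=30.0, K_B=20.0, E0=10.0)
        a = np.array([5.0, 30.0, 200.0])
        b = np.full(3, 40.0)
        rate = pingpong_rate(truth, a, b) * np.array([1.04, 0.97, 1.01])
        grid = RateGrid(a, b, rate, np.zeros(3), truth.E0)
        res = fit_cosubstrate_constrained(grid, {"K_B": truth.K_B})

        kc = np.geomspace(10, 250, 220)
        ka = np.geomspace(3, 300, 220)
        best = (np.inf, None, None)
        for k in kc:
            pred = np.array(
                [
                    pingpong_rate(
                        RateLawParams(kcat=k, K_A=K, K_B=truth.K_B, E0=truth.E0), a, b
                    )
                    for K in ka
                ]
            )
            rss = ((pred - rate) ** 2).sum(axis=1)
            i = int(np.argmin(rss))
            if rss[i] < best[0]:
                best = (rss[i], k, ka[i])
        assert res.rss <= best[0] + 1e-12
        # lattice resolution is ~1.5% per step in each axis
        assert res.params.kcat == pytest.approx(best[1], rel=0.03)
        assert res.params.K_A == pytest.approx(best[2], rel=0.03)


class TestInhibitionSelection:
    def test_no_inhibition_truth_reported_nd(self, human_truth):
        grid = sim.simulate_rate_grid(sim.human_bnah_scenario(seed=21))
        res = select_inhibition_model(grid)
        assert res.inhibition_detected == "ND"
        assert res.params.K_I is None

    def test_nd_rate_under_null_at_least_90pc(self):
        seeds = replicate_seeds(210, 60)
        nd = 0
        for s in seeds:
            grid = sim.simulate_rate_grid(sim.human_bnah_scenario(seed=int(s)))
            nd += select_inhibition_model(grid).inhibition_detected == "ND"
        assert nd >= 0.90 * len(seeds)

    def test_duck_inhibition_retained_with_dense_acceptor_coverage(self, duck_truth):
        grid = sim.simulate_rate_grid(sim.duck_bnah_scenario(seed=33))
        res = select_inhibition_model(grid)
        assert res.inhibition_detected == "yes"
        lo, hi = res.conf_int()["K_I"]
        assert lo < duck_truth.K_I < hi

    def test_selection_deterministic_for_identical_data(self, human_truth):
        grid = sim.simulate_rate_grid(sim.human_bnah_scenario(seed=44))
        r1 = select_inhibition_model(grid)
        r2 = select_inhibition_model(grid)
        assert r1.inhibition_detected == r2.inhibition_detected
        assert r1.rss == r2.rss


class TestConstrainedFit:
    def test_noise_free_alligator_nadh_round_trip(self):
        truth = sim.PRESET_TRUTHS["alligator_nadh"]
        grid = noise_free_grid(
            truth, sim.NADH_LEVELS, [40.0], cosubstrate="NADH"
        )
        res = fit_cosubstrate_constrained(grid, {"K_B": 36.0, "K_I": 24.0})
        assert res.params.kcat == pytest.approx(truth.kcat, rel=1e-6)
        assert res.params.K_A == pytest.approx(truth.K_A, rel=1e-6)

    def test_missing_frozen_constants_is_configuration_error(self, human_truth):
        grid = noise_free_grid(human_truth, sim.BNAH_LEVELS, sim.MENADIONE_LEVELS)
        with pytest.raises(ValueError):
            fit_cosubstrate_constrained(grid, {"K_I": 24.0})

    def test_sub_saturating_range_flags_unsaturated(self):
        truth = sim.PRESET_TRUTHS["alligator_nadh"]
        a = np.geomspace(40.0, truth.K_A / 10.0, 8)  # capped at K_A/10
        grid = noise_free_grid(truth, a, [40.0], cosubstrate="NADH")
        res = fit_cosubstrate_constrained(grid, {"K_B": 36.0, "K_I": 24.0})
        assert not res.saturated

    def test_efficiency_robust_to_frozen_KB_error_in_linear_regime(self):
        truth = sim.PRESET_TRUTHS["alligator_nadh"]
        a = np.geomspace(40.0, truth.K_A / 5.0, 8)
        grid = noise_free_grid(truth, a, [20.0, 40.0], cosubstrate="NADH")
        effs = []
        for factor in (0.5, 1.0, 1.5):
            res = fit_cosubstrate_constrained(
                grid, {"K_B": 36.0 * factor, "K_I": 24.0}
            )
            effs.append(res.efficiency.value)
        assert abs(effs[0] / effs[1] - 1) < 0.05
        assert abs(effs[2] / effs[1] - 1) < 0.05


class TestEfficiencyOnlyFit:
    @staticmethod
    def linear_regime_grid(efficiency_M_s, E0_nM=15000.0, K_I=11.0):
        a = np.repeat(np.geomspace(40.0, 12000.0, 8), 6)
        b = np.tile(np.repeat([20.0, 40.0], 3), 8)
        rep = np.tile([0, 1, 2, 0, 1, 2], 8)
        slope = E0_nM * 1e-3 * efficiency_M_s * 1e-6  # s⁻¹
        rate = slope * a / (1.0 + b / K_I)
        return RateGrid(a, b, rate, rep, E0_nM, cosubstrate="NADPH")

    def test_duck_nadph_efficiency_round_trip(self):
        grid = self.linear_regime_grid(1.8)
        res = fit_efficiency_only(grid, {"K_B": 3.5, "K_I": 11.0})
        assert res.efficiency.value == pytest.approx(1.8, rel=1e-6)
        assert res.to_dict()["params"]["kcat"] == "ND"
        assert res.to_dict()["params"]["K_A"] == "ND"

    def test_all_zero_rates_degenerate(self):
        grid = self.linear_regime_grid(1.8)
        zero = RateGrid(
            grid.a, grid.b, np.zeros_like(grid.rate), grid.replicate,
            grid.enzyme_nM, cosubstrate="NADPH",
        )
        res = fit_efficiency_only(zero, {"K_B": 3.5, "K_I": 11.0})
        assert res.efficiency.value == 0.0
        assert np.isinf(res.efficiency.relative_ci_width)
        assert "degenerate" in res.flags

    def test_refuses_clearly_saturating_grid(self):
        truth = sim.PRESET_TRUTHS["duck_nadh"]  # K_A = 1,600 << max a
        grid = noise_free_grid(
            truth, sim.NADH_LEVELS, sim.NADH_MENADIONE_LEVELS, cosubstrate="NADH"
        )
        with pytest.raises(SaturationError):
            fit_efficiency_only(grid, {"K_B": 3.5, "K_I": 11.0})

    def test_agrees_with_constrained_fit_on_sub_saturating_data(self):
        # strongly sub-saturating: with b fixed, the apparent Michaelis
        # constant is K_A·b/(K_B + b) ≈ 10,200 µM for the human NADH truth,
        # so capping a at ~1 mM keeps the response within ~10% of linear
        truth = sim.PRESET_TRUTHS["human_nadh"]
        scn = sim.KineticScenario(
            truth, np.geomspace(40.0, 1000.0, 8), sim.NADH_MENADIONE_LEVELS,
            seed=55, cosubstrate="NADH",
        )
        grid = sim.simulate_rate_grid(scn)
        r_lin = fit_efficiency_only(grid, {"K_B": 65.0})
        r_con = fit_cosubstrate_constrained(grid, {"K_B": 65.0})
        lo1, hi1 = r_lin.efficiency.ci95
        lo2, hi2 = r_con.efficiency.ci95
        assert max(lo1, lo2) < min(hi1, hi2)  # intervals overlap
        assert r_lin.efficiency.value == pytest.approx(
            truth.efficiency, rel=0.25
        )


class TestCatalyticEfficiency:
    def test_unit_conversion_identity(self):
        assert efficiency_from_constants(12.5, 12.5) == pytest.approx(1e6, rel=1e-12)

    def test_point_value_from_params(self):
        p = RateLawParams(kcat=1190.0, K_A=96.0, K_B=65.0, E0=0.46)
        est = catalytic_efficiency(p)
        assert est.value == pytest.approx(1190.0 / 96e-6, rel=1e-12)

    def test_ci_from_fit_covariance(self, human_truth):
        grid = sim.simulate_rate_grid(sim.human_bnah_scenario(seed=66))
        res = fit_global_pingpong(grid)
        est = catalytic_efficiency(res)
        assert est.ci95[0] < est.value < est.ci95[1]
        assert est.se > 0
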