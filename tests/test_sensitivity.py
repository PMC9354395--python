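import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btc_cea import (
    build_tornado,
    calibrate_distribution,
    ceac,
    default_wtp_grid,
    one_way_sweep,
    run_psa,
    run_strategy,
)
from btc_cea.sensitivity import psa_distributions


class TestDistributionCalibration:
    def test_beta_for_pfs_utility_matches_hand_computation(self):
        # mean 0.69, sd (0.925-0.455)/3.92: method-of-moments alpha/beta
        spec = calibrate_distribution(0.69, 0.455, 0.925, "beta")
        assert spec.params["alpha"] == pytest.approx(9.5768, abs=0.001)
        assert spec.params["beta"] == pytest.approx(4.3026, abs=0.001)

    def test_gamma_for_oxaliplatin_cost_matches_hand_computation(self):
        spec = calibrate_distribution(304.45, 243.56, 365.34, "gamma")
        assert spec.params["shape"] == pytest.approx(96.04, abs=0.01)
        assert spec.params["scale"] == pytest.approx(3.1700, abs=0.001)

    def test_degenerate_range_returns_point_mass(self):
        spec = calibrate_distribution(0.5, 0.5, 0.5, "beta")
        rng = np.random.default_rng(0)
        assert spec.family == "degenerate"
        assert spec.sample(rng) == 0.5

    def test_beta_requires_baseline_in_unit_interval(self):
        with pytest.raises(ValueError):
            calibrate_distribution(1.2, 1.0, 1.4, "beta")

    def test_baseline_outside_range_rejected(self):
        with pytest.raises(ValueError):
            calibrate_distribution(2.0, 3.0, 4.0, "gamma")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mean=st.floats(0.05, 0.95),
        halfwidth=st.floats(0.01, 0.2),
    )
    def test_beta_moments_match_request(self, mean, halfwidth):
        lo, hi = max(mean - halfwidth, 0.0), min(mean + halfwidth, 1.0)
        spec = calibrate_distribution(mean, lo, hi, "beta")
        a, b = spec.params["alpha"], spec.params["beta"]
        assert a / (a + b) == pytest.approx(mean, abs=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(((hi - lo) / 3.92) ** 2, rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mean=st.floats(1.0, 5000.0), rel=st.floats(0.05, 0.5))
    def test_gamma_moments_match_request(self, mean, rel):
        lo, hi = mean * (1 - rel), mean * (1 + rel)
        spec = calibrate_distribution(mean, lo, hi, "gamma")
        assert spec.params["shape"] * spec.params["scale"] == pytest.approx(mean)
        var = spec.params["shape"] * spec.params["scale"] ** 2
        assert var == pytest.approx(((hi - lo) / 3.92) ** 2, rel=1e-6)


class TestOneWaySweeps:
    def test_degenerate_parameter_gives_zero_width(self, default_config):
        entry = one_way_sweep(default_config, "sae_cost.stomatitis")
        assert entry.width == 0.0
        assert entry.icer_low == entry.icer_high

    def test_unknown_parameter_rejected(self, default_config):
        with pytest.raises(KeyError):
            one_way_sweep(default_config, "not_a_parameter")

    def test_gemcitabine_cost_shifts_gemox_arm_linearly(self, default_config):
        u = default_config.uncertain_parameters()["drug_cost.gemcitabine"]
        base_x = run_strategy(default_config, "XELOX").total_cost
        base_g = run_strategy(default_config, "GEMOX").total_cost
        lo_cfg = default_config.with_overrides({"drug_cost.gemcitabine": u.low})
        hi_cfg = default_config.with_overrides({"drug_cost.gemcitabine": u.high})
        # XELOX unaffected; GEMOX moves linearly (symmetric +-20% bounds)
        assert run_strategy(lo_cfg, "XELOX").total_cost == pytest.approx(base_x)
        drop = base_g - run_strategy(lo_cfg, "GEMOX").total_cost
        rise = run_strategy(hi_cfg, "GEMOX").total_cost - base_g
        assert drop == pytest.approx(rise, rel=1e-9)
        assert drop > 0

    def test_dominance_holds_at_every_configured_bound(self, default_config):
        """XELOX stays cheaper and more effective across all one-way sweeps."""
        from btc_cea import compare_strategies

        for name, u in default_config.uncertain_parameters().items():
            for bound in (u.low, u.high):
                cfg = default_config.with_overrides({name: bound})
                inc = compare_strategies(
                    run_strategy(cfg, "XELOX"), run_strategy(cfg, "GEMOX")
                )
                assert inc.dominance == "dominant", f"{name} at {bound}"


class TestTornado:
    def test_entries_are_a_sorted_permutation_of_the_registry(self, default_config):
        entries = build_tornado(default_config)
        names = [e.parameter for e in entries]
        assert sorted(names) == sorted(default_config.uncertain_parameters())
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_gemcitabine_cost_is_the_top_driver(self, default_config):
        entries = build_tornado(default_config)
        assert entries[0].parameter == "drug_cost.gemcitabine"

    def test_collapsed_ranges_give_all_zero_widths(self, default_config):
        data = default_config.to_dict()
        cfg = default_config
        collapsed = cfg.with_overrides({})  # fresh copy
        for name, u in cfg.uncertain_parameters().items():
            container, key = collapsed._value_path(name)
            container["low"] = container["high"] = container[key]
        entries = build_tornado(collapsed)
        assert all(e.width == 0.0 for e in entries)
        assert data == default_config.to_dict()  # no mutation of the original


class TestPSA:
    def test_fixed_seed_reproducible(self, default_config):
        a = run_psa(default_config, n_iter=20, seed=5)
        b = run_psa(default_config, n_iter=20, seed=5)
        assert a == b

    def test_sampled_values_respect_supports(self, psa_samples):
        for s in psa_samples[:200]:
            for name, value in s.parameters.items():
                if name.startswith("utility.") or name.startswith("sae_rate."):
                    assert 0.0 <= value <= 1.0, name
                else:
                    assert value >= 0.0, name

    def test_sample_means_converge_to_baselines(self, default_config, psa_samples):
        registry = default_config.uncertain_parameters()
        for name in ("utility.pfs", "drug_cost.gemcitabine", "bsc"):
            draws = np.array([s.parameters[name] for s in psa_samples])
            assert draws.mean() == pytest.approx(registry[name].value, rel=0.02)

    def test_table1_curves_and_bsa_are_not_sampled(self, default_config):
        dists = psa_distributions(default_config)
        assert "bsa" not in dists
        assert not any("lam" in k or "gamma" in k for k in dists)

    def test_degenerate_distributions_reproduce_base_case(self, default_config):
        collapsed = default_config.with_overrides({})
        for name in default_config.uncertain_parameters():
            container, key = collapsed._value_path(name)
            container["low"] = container["high"] = container[key]
        samples = run_psa(collapsed, n_iter=3, seed=0)
        base = {
            s: (run_strategy(default_config, s).total_cost,
                run_strategy(default_config, s).total_qaly)
            for s in default_config.strategy_names
        }
        for s in samples:
            for strat, (cost, qaly) in s.outcomes.items():
                assert cost == pytest.approx(base[strat][0])
                assert qaly == pytest.approx(base[strat][1])

    def test_invalid_iteration_count_rejected(self, default_config):
        with pytest.raises(ValueError):
            run_psa(default_config, n_iter=0, seed=0)


class TestCEAC:
    def test_probabilities_sum_to_one_on_default_grid(
        self, default_config, psa_samples
    ):
        points = ceac(psa_samples, default_wtp_grid(default_config))
        for p in points:
            assert sum(p.probability.values()) == pytest.approx(1.0)
            assert all(0.0 <= v <= 1.0 for v in p.probability.values())

    def test_dominant_strategy_is_favoured_across_grid(
        self, default_config, psa_samples
    ):
        points = ceac(psa_samples, default_wtp_grid(default_config))
        assert all(p.probability["XELOX"] >= 0.5 for p in points)

    def test_single_draw_gives_degenerate_curve(self, default_config):
        samples = run_psa(default_config, n_iter=1, seed=3)
        points = ceac(samples, [0.0, 31315.24])
        for p in points:
            assert set(p.probability.values()) <= {0.0, 1.0}

    def test_empty_inputs_rejected(self, default_config, psa_samples):
        with pytest.raises(ValueError):
            ceac([], [1000.0])
        with pytest.raises(ValueError):
            ceac(psa_samples, [])
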