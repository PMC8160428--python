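import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from germfilter.simulate import (
    SimulationConfig,
    SpeciesSimParams,
    TRIAL_GRID,
    draw_species_pool,
    simulate_quadrats,
    simulate_trials,
    true_btn,
    true_germination_probability,
)
from germfilter.types import StorageTreatment, TemperatureCondition, ValidationError


def params(**kw):
    defaults = dict(
        species_id="sp", p_max=0.8, t_opt=15.0, t_sd=5.0, alt_effect=0.5,
        coldstrat_effect=0.3, timing_hazard=0.2, base_log_abundance=0.0,
        n_response_slope=0.0,
    )
    defaults.update(kw)
    return SpeciesSimParams(**defaults)


class TestTrueGerminationProbability:
    def test_peak_at_optimum_equals_p_max(self):
        sp = params(t_opt=20.0)
        assert true_germination_probability(sp, TemperatureCondition.T20) == pytest.approx(0.8)

    def test_zero_alt_effect_matches_15_degrees(self):
        sp = params(alt_effect=0.0)
        p_alt = true_germination_probability(sp, TemperatureCondition.ALT_5_25)
        p_15 = true_germination_probability(sp, TemperatureCondition.T15)
        assert p_alt == pytest.approx(p_15, abs=1e-12)

    def test_gaussian_curve_arithmetic(self):
        sp = params(p_max=0.8, t_opt=15.0, t_sd=5.0)
        p = true_germination_probability(sp, TemperatureCondition.T20)
        assert p == pytest.approx(0.8 * np.exp(-25.0 / 50.0), abs=1e-5)
        assert p == pytest.approx(0.48522, abs=1e-5)

    def test_cold_stratification_shifts_logit(self):
        sp = params(coldstrat_effect=1.0)
        p_dry = true_germination_probability(sp, TemperatureCondition.ALT_5_25)
        p_wc = true_germination_probability(
            sp, TemperatureCondition.ALT_5_25, StorageTreatment.DRY_WARM_WET_COLD
        )
        logit = lambda p: np.log(p / (1 - p))
        assert logit(p_wc) - logit(p_dry) == pytest.approx(1.0, abs=1e-9)


class TestDrawSpeciesPool:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_species=3, rng_seed=1)
        assert draw_species_pool(cfg) == draw_species_pool(cfg)

    def test_different_seeds_differ(self):
        a = draw_species_pool(SimulationConfig(n_species=3, rng_seed=1))
        b = draw_species_pool(SimulationConfig(n_species=3, rng_seed=2))
        assert a != b

    def test_no_coupling_no_noise_gives_zero_slopes(self):
        cfg = SimulationConfig(n_species=5, noise_sd=0.0, rng_seed=3)
        assert all(sp.n_response_slope == 0.0 for sp in draw_species_pool(cfg))

    def test_btn_coupling_orders_slopes_by_true_btn(self):
        cfg = SimulationConfig(n_species=30, coupling={"BTN": 1.0}, noise_sd=0.0, rng_seed=4)
        pool = draw_species_pool(cfg)
        slopes = np.array([sp.n_response_slope for sp in pool])
        btns = np.array([true_btn(sp) for sp in pool])
        assert np.array_equal(np.argsort(slopes), np.argsort(btns))

    def test_unknown_coupling_key_rejected(self):
        with pytest.raises(ValidationError, match="coupling"):
            SimulationConfig(coupling={"height": 1.0})


class TestSimulateTrials:
    def test_condition_grid_size(self):
        cfg = SimulationConfig(n_species=4, rng_seed=5)
        trials = simulate_trials(draw_species_pool(cfg), cfg)
        # 6 regimes after dry-warm storage + the alternating regime after
        # wet-cold storage, 3 replicates each
        assert len(trials) == 4 * 7 * 3
        assert len(TRIAL_GRID) == 7

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_species=3, rng_seed=6)
        pool = draw_species_pool(cfg)
        assert simulate_trials(pool, cfg) == simulate_trials(pool, cfg)

    def test_hazard_one_puts_all_germination_on_day_one(self):
        cfg = SimulationConfig(n_species=2, rng_seed=7)
        pool = [dataclasses.replace(sp, timing_hazard=1.0) for sp in draw_species_pool(cfg)]
        for t in simulate_trials(pool, cfg):
            assert sum(t.daily_counts[1:]) == 0

    def test_vanishing_p_max_gives_no_germination(self):
        cfg = SimulationConfig(n_species=2, rng_seed=8)
        pool = [
            dataclasses.replace(sp, p_max=1e-8, alt_effect=0.0, coldstrat_effect=0.0)
            for sp in draw_species_pool(cfg)
        ]
        assert all(t.total_germinated == 0 for t in simulate_trials(pool, cfg))

    def test_binomial_consistency_of_mean_gp(self):
        """With many replicates at fixed p, pooled GP ~ p within 3 SE."""
        from germfilter.traits import germination_percentage

        cfg = SimulationConfig(
            n_species=1, replicates=200, seeds_per_replicate=50, rng_seed=9
        )
        sp = params(p_max=0.6, t_opt=15.0, t_sd=1e6, timing_hazard=1.0)
        p = true_germination_probability(sp, TemperatureCondition.T15)
        trials = [
            t for t in simulate_trials([sp], cfg)
            if t.condition is TemperatureCondition.T15
            and t.storage is StorageTreatment.DRY_WARM
        ]
        n_total = 200 * 50
        gp = germination_percentage(trials)
        assert abs(gp - p) < 3 * np.sqrt(p * (1 - p) / n_total)


class TestSimulateQuadrats:
    def test_deterministic_and_design_shape(self):
        cfg = SimulationConfig(n_species=5, n_blocks=3, rng_seed=10)
        pool = draw_species_pool(cfg)
        q1 = simulate_quadrats(pool, cfg)
        q2 = simulate_quadrats(pool, cfg)
        assert q1 == q2
        assert len(q1) == 3 * 4

    def test_single_species_holds_whole_count(self):
        cfg = SimulationConfig(n_species=1, n_blocks=2, rng_seed=11)
        pool = draw_species_pool(cfg)
        for q in simulate_quadrats(pool, cfg):
            assert list(q.species_counts) == [pool[0].species_id]
            assert q.total_individuals > 0

    def test_no_slope_no_block_sd_keeps_composition_stable_across_doses(self):
        cfg = SimulationConfig(
            n_species=6, n_blocks=1, noise_sd=0.0, block_sd=0.0,
            quadrat_total_individuals=2e5, rng_seed=12,
        )
        pool = draw_species_pool(cfg)
        quadrats = simulate_quadrats(pool, cfg)
        props = np.array(
            [
                [q.species_counts.get(sp.species_id, 0) / q.total_individuals for sp in pool]
                for q in quadrats
            ]
        )
        assert np.abs(props - props[0]).max() < 0.01

    def test_strong_btn_coupling_recovers_in_empirical_rf(self):
        """Downstream R_f rank-correlates with true BTN under pure coupling."""
        from germfilter.community import compute_abundance_responses

        cfg = SimulationConfig(
            n_species=40, coupling={"BTN": 2.0}, noise_sd=0.0, block_sd=0.0,
            quadrat_total_individuals=1e5, rng_seed=7,
        )
        pool = draw_species_pool(cfg)
        responses = compute_abundance_responses(simulate_quadrats(pool, cfg))
        btn = {sp.species_id: true_btn(sp) for sp in pool}
        pairs = [(btn[r.species_id], r.r_f) for r in responses if r.r_f is not None]
        rho = spearmanr([p[0] for p in pairs], [p[1] for p in pairs]).statistic
        assert rho > 0.8
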