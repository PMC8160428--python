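import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germfilter.traits import (
    build_profiles,
    germination_percentage,
    germination_rate,
    niche_metrics,
    profiles_to_frame,
    response_alternating,
    response_wet_cold,
)
from germfilter.types import StorageTreatment, TemperatureCondition, ValidationError
from tests.conftest import make_trial, random_trials_for_species
from tests import oracles

TEMPS = (5.0, 10.0, 15.0, 20.0, 25.0)


class TestGerminationPercentage:
    def test_single_replicate(self):
        t = make_trial(days_counts=[(1, 12), (5, 8)])
        assert germination_percentage([t]) == pytest.approx(0.40)

    def test_pooled_ratio_of_sums(self):
        trials = [
            make_trial(replicate=i + 1, days_counts=[(2, total)])
            for i, total in enumerate((10, 20, 30))
        ]
        assert germination_percentage(trials) == pytest.approx(60 / 150)

    def test_zero_counts(self):
        assert germination_percentage([make_trial()]) == 0.0

    def test_mixed_units_rejected(self):
        a = make_trial(species="spA")
        b = make_trial(species="spB")
        with pytest.raises(ValidationError):
            germination_percentage([a, b])


class TestGerminationRate:
    def test_all_on_day_one_is_upper_bound(self):
        t = make_trial(days_counts=[(1, 50)])
        assert germination_rate([t]) == pytest.approx(1.0)

    def test_day_weighted_arithmetic(self):
        t = make_trial(days_counts=[(1, 10), (2, 10)])
        assert germination_rate([t]) == pytest.approx((10 / 1 + 10 / 2) / 50)

    def test_no_germination(self):
        assert germination_rate([make_trial()]) == 0.0

    def test_gr_never_exceeds_gp(self, rng):
        for _ in range(50):
            trials = random_trials_for_species(rng, "sp")[:3]
            assert germination_rate(trials) <= germination_percentage(trials) + 1e-12


class TestResponses:
    @pytest.mark.parametrize(
        "fn,a,b,expected",
        [
            (response_alternating, 0.4, 0.4, 0.0),
            (response_alternating, 0.6, 0.2, 0.5),
            (response_alternating, 0.0, 0.0, None),
            (response_wet_cold, 0.8, 0.0, 1.0),
            (response_wet_cold, 0.3, 0.3, 0.0),
            (response_wet_cold, 0.3, 0.6, -1 / 3),
        ],
    )
    def test_normalized_difference(self, fn, a, b, expected):
        result = fn(a, b)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)


class TestNicheMetrics:
    def test_flat_profile_is_maximal_breadth(self):
        occ, prop, btn = niche_metrics({t: 0.3 for t in TEMPS})
        assert all(o == 1.0 for o in occ.values())
        assert all(p == pytest.approx(0.2) for p in prop.values())
        assert btn == pytest.approx(1.0)

    def test_single_temperature_is_minimal_breadth(self):
        gps = {t: (0.5 if t == 15.0 else 0.0) for t in TEMPS}
        occ, prop, btn = niche_metrics(gps)
        assert occ[15.0] == 1.0 and sum(occ.values()) == 1.0
        assert prop[15.0] == 1.0
        assert btn == pytest.approx(0.2)  # 1/R with R = 5

    def test_unimodal_arithmetic(self):
        gps = dict(zip(TEMPS, (0.2, 0.4, 0.8, 0.4, 0.2)))
        occ, prop, btn = niche_metrics(gps)
        assert [occ[t] for t in TEMPS] == pytest.approx([0.25, 0.5, 1.0, 0.5, 0.25])
        assert btn == pytest.approx(0.5)
        assert [prop[t] for t in TEMPS] == pytest.approx([0.1, 0.2, 0.4, 0.2, 0.1])

    def test_no_germination_undefined(self):
        occ, prop, btn = niche_metrics({t: 0.0 for t in TEMPS})
        assert occ is None and prop is None and btn is None

    def test_wrong_temperature_set_rejected(self):
        with pytest.raises(ValidationError):
            niche_metrics({5.0: 0.1, 10.0: 0.2})

    @given(
        gps=st.lists(st.floats(0.001, 1.0), min_size=5, max_size=5),
        scale=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_proportions_sum_to_one_and_btn_scale_free(self, gps, scale):
        base = dict(zip(TEMPS, gps))
        occ, prop, btn = niche_metrics(base)
        assert sum(prop.values()) == pytest.approx(1.0, abs=1e-12)
        assert max(occ.values()) == 1.0
        _, _, btn_scaled = niche_metrics({t: g * scale for t, g in base.items()})
        assert btn_scaled == pytest.approx(btn, abs=1e-12)
        assert 1 / 5 <= btn <= 1.0


class TestBuildProfiles:
    def test_instant_full_germination_limit(self):
        from germfilter.simulate import TRIAL_GRID

        trials = [
            make_trial(condition=c, storage=s, replicate=r, days_counts=[(1, 50)])
            for c, s in TRIAL_GRID
            for r in (1, 2, 3)
        ]
        (profile,) = build_profiles(trials)
        assert all(v == pytest.approx(1.0) for v in profile.gp.values())
        assert all(v == pytest.approx(1.0) for v in profile.gr.values())
        assert profile.btn == pytest.approx(1.0)
        assert profile.r_alt == pytest.approx(0.0)
        assert profile.r_wc == pytest.approx(0.0)

    def test_zero_germination_everywhere_is_undefined_with_reason(self):
        from germfilter.simulate import TRIAL_GRID

        trials = [
            make_trial(condition=c, storage=s, replicate=r)
            for c, s in TRIAL_GRID
            for r in (1, 2, 3)
        ]
        (profile,) = build_profiles(trials)
        assert profile.btn is None
        assert profile.r_alt is None and profile.r_wc is None
        assert profile.reasons["BTN"] == "no_germination"
        assert profile.reasons["R_5_25"] == "no_germination"

    def test_missing_condition_leaves_reason_code(self):
        trials = [
            make_trial(condition=TemperatureCondition.T15, replicate=r, days_counts=[(1, 5)])
            for r in (1, 2, 3)
        ]
        (profile,) = build_profiles(trials)
        assert profile.gp["T5"] is None
        assert profile.reasons["GP_T5"] == "missing_condition"
        assert profile.btn is None
        assert profile.reasons["BTN"] == "missing_condition"

    def test_profiles_match_bruteforce_oracle(self, rng):
        """Random trials: every index equals a naive recomputation exactly."""
        trials = []
        for i in range(30):
            trials.extend(random_trials_for_species(rng, f"sp{i:02d}"))
        profiles = build_profiles(trials)
        by_unit = {}
        for t in trials:
            by_unit.setdefault((t.species_id, t.condition, t.storage), []).append(t)
        for p in profiles:
            gps = {}
            for c in TemperatureCondition:
                unit = by_unit[(p.species_id, c, StorageTreatment.DRY_WARM)]
                assert p.gp[c.name] == oracles.oracle_gp(unit)
                assert p.gr[c.name] == pytest.approx(
                    oracles.oracle_gr_mean(unit), abs=1e-15
                )
                if c.is_constant:
                    gps[c.nominal_mean_celsius] = p.gp[c.name]
            occ, prop, btn = oracles.oracle_niche(gps)
            if btn is None:
                assert p.btn is None
            else:
                assert p.btn == pytest.approx(btn, abs=1e-12)
                for t in TEMPS:
                    assert p.occupation[t] == pytest.approx(occ[t], abs=1e-12)
                    assert p.proportion_niche[t] == pytest.approx(prop[t], abs=1e-12)
            gp_alt = p.gp["ALT_5_25"]
            wc_unit = by_unit[
                (p.species_id, TemperatureCondition.ALT_5_25, StorageTreatment.DRY_WARM_WET_COLD)
            ]
            expected_rwc = oracles.oracle_ratio_response(oracles.oracle_gp(wc_unit), gp_alt)
            expected_ralt = oracles.oracle_ratio_response(gp_alt, p.gp["T15"])
            assert (p.r_wc is None) == (expected_rwc is None)
            assert (p.r_alt is None) == (expected_ralt is None)
            if expected_rwc is not None:
                assert p.r_wc == pytest.approx(expected_rwc, abs=1e-15)
            if expected_ralt is not None:
                assert p.r_alt == pytest.approx(expected_ralt, abs=1e-15)

    def test_monotonicity_in_counts_and_timing(self):
        base = make_trial(days_counts=[(3, 10), (8, 5)])
        more = make_trial(days_counts=[(3, 10), (8, 5), (10, 4)])
        earlier = make_trial(days_counts=[(2, 10), (8, 5)])
        assert germination_percentage([more]) > germination_percentage([base])
        assert germination_rate([more]) > germination_rate([base])
        assert germination_rate([earlier]) > germination_rate([base])

    def test_frame_round_trip_preserves_values(self, rng):
        from germfilter.traits import frame_to_profiles

        trials = []
        for i in range(5):
            trials.extend(random_trials_for_species(rng, f"sp{i}"))
        profiles = build_profiles(trials)
        back = frame_to_profiles(profiles_to_frame(profiles))
        for a, b in zip(profiles, back):
            assert a.species_id == b.species_id
            assert a.btn == (b.btn if b.btn is None else pytest.approx(b.btn, abs=1e-12))
            assert (a.r_wc is None) == (b.r_wc is None)
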