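import numpy as np
import pytest
from scipy.stats import ortho_group

from germfilter.fd import (
    FD_TRAIT_VARIABLES,
    TraitSpace,
    build_trait_space,
    fd_all,
    fdiv,
    feve,
    fric,
)
from germfilter.simulate import SimulationConfig, draw_species_pool, simulate_quadrats, simulate_trials
from germfilter.traits import build_profiles
from germfilter.types import ValidationError
from tests import oracles


def space_from(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return TraitSpace(species_ids=list(ids), coordinates=points, axes_used=points.shape[1])


def equal_weights(space):
    return {sp: 1.0 for sp in space.species_ids}


class TestFRic:
    def test_unit_right_triangle_has_area_half(self):
        space = space_from([(0, 0), (1, 0), (0, 1)])
        assert fric(space, equal_weights(space)) == pytest.approx(0.5)

    def test_collinear_points_undefined(self):
        space = space_from([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert fric(space, equal_weights(space)) is None

    def test_too_few_points_undefined(self):
        space = space_from([(0, 0), (1, 0)])
        assert fric(space, equal_weights(space)) is None

    def test_matches_independent_volume_oracle(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 4))
            s = int(rng.integers(m + 2, 13))
            pts = rng.normal(size=(s, m))
            space = space_from(pts)
            vol = fric(space, equal_weights(space))
            assert vol == pytest.approx(oracles.oracle_hull_volume(pts), rel=0.01)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(10, 3))
        q = ortho_group.rvs(3, random_state=np.random.RandomState(5))
        a = fric(space_from(pts), equal_weights(space_from(pts)))
        b = fric(space_from(pts @ q), equal_weights(space_from(pts)))
        assert b == pytest.approx(a, rel=1e-9)

    def test_monotone_under_species_addition(self, rng):
        pts = rng.normal(size=(12, 2))
        space = space_from(pts)
        full = fric(space, equal_weights(space))
        subset = fric(space, {f"s{i}": 1.0 for i in range(8)})
        if subset is not None:
            assert full >= subset - 1e-12


class TestFEve:
    def test_equally_spaced_collinear_equal_weights_is_one(self):
        space = space_from([(i, 0.0) for i in range(5)])
        assert feve(space, equal_weights(space)) == pytest.approx(1.0)

    def test_imbalance_decreases_evenness(self):
        space = space_from([(0, 0), (1, 0), (10, 0)])
        balanced = feve(space_from([(0, 0), (1, 0), (2, 0)]),
                        {"s0": 1, "s1": 1, "s2": 1})
        skewed = feve(space, {"s0": 1, "s1": 1, "s2": 1})
        assert skewed < balanced

    def test_fewer_than_three_species_undefined(self):
        space = space_from([(0, 0), (1, 0)])
        assert feve(space, equal_weights(space)) is None

    def test_weight_scale_invariance(self, rng):
        pts = rng.normal(size=(8, 2))
        space = space_from(pts)
        w = {f"s{i}": float(rng.uniform(0.1, 5)) for i in range(8)}
        w10 = {k: 10 * v for k, v in w.items()}
        assert feve(space, w10) == pytest.approx(feve(space, w), abs=1e-12)

    def test_matches_prim_mst_oracle(self, rng):
        for _ in range(40):
            m = int(rng.integers(1, 4))
            s = int(rng.integers(3, 13))
            pts = rng.normal(size=(s, m))
            w = rng.uniform(0.05, 3.0, s)
            space = space_from(pts)
            community = {f"s{i}": float(w[i]) for i in range(s)}
            assert feve(space, community) == pytest.approx(
                oracles.oracle_feve(pts, w), abs=1e-9
            )


class TestFDiv:
    def test_equidistant_species_give_one(self):
        # regular simplex vertices are equidistant from their centroid
        space = space_from([(1, 0), (-0.5, np.sqrt(3) / 2), (-0.5, -np.sqrt(3) / 2)])
        assert fdiv(space, equal_weights(space)) == pytest.approx(1.0)

    def test_abundance_near_centroid_pulls_below_half(self):
        pts = [(1, 0), (-0.5, np.sqrt(3) / 2), (-0.5, -np.sqrt(3) / 2), (0.01, 0.0)]
        space = space_from(pts)
        w = {"s0": 0.01, "s1": 0.01, "s2": 0.01, "s3": 10.0}
        assert fdiv(space, w) < 0.5

    def test_weight_scale_invariance(self, rng):
        pts = rng.normal(size=(9, 2))
        space = space_from(pts)
        w = {f"s{i}": float(rng.uniform(0.1, 5)) for i in range(9)}
        w3 = {k: 3 * v for k, v in w.items()}
        assert fdiv(space, w3) == pytest.approx(fdiv(space, w), abs=1e-12)

    def test_matches_direct_formula_oracle_with_independent_hull(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 4))
            s = int(rng.integers(m + 2, 13))
            pts = rng.normal(size=(s, m))
            w = rng.uniform(0.05, 3.0, s)
            space = space_from(pts)
            community = {f"s{i}": float(w[i]) for i in range(s)}
            got = fdiv(space, community)
            assert got == pytest.approx(oracles.oracle_fdiv(pts, w), abs=1e-9)
            assert 0.0 <= got <= 1.0


@pytest.fixture(scope="module")
def study():
    cfg = SimulationConfig(n_species=20, n_blocks=3, rng_seed=31, duration_days=30)
    pool = draw_species_pool(cfg)
    profiles = build_profiles(simulate_trials(pool, cfg))
    quadrats = simulate_quadrats(pool, cfg)
    return profiles, quadrats


class TestTraitSpace:
    def test_species_missing_a_variable_is_dropped_with_reason(self, study):
        profiles, _ = study
        import copy

        mutated = [copy.deepcopy(p) for p in profiles]
        victim = mutated[0]
        victim.r_wc = None
        space = build_trait_space(mutated, m=7)
        dropped = dict(space.dropped_species)
        assert victim.species_id in dropped
        assert "R_wc" in dropped[victim.species_id]

    def test_zero_variance_column_is_named(self, study):
        profiles, _ = study
        import copy

        mutated = [copy.deepcopy(p) for p in profiles]
        for p in mutated:
            p.r_wc = 0.25
        with pytest.raises(ValidationError, match="R_wc"):
            build_trait_space(mutated, m=7)

    def test_auto_dimensionality_bounded_by_poorest_community(self, study):
        profiles, quadrats = study
        space = build_trait_space(profiles, "auto", quadrats)
        kept = set(space.species_ids)
        s_min = min(
            sum(1 for sp, n in q.species_counts.items() if n > 0 and sp in kept)
            for q in quadrats
        )
        assert space.axes_used == min(len(FD_TRAIT_VARIABLES), max(2, s_min - 1))

    def test_full_rank_space_keeps_standardized_traits(self, study):
        profiles, _ = study
        space = build_trait_space(profiles, m=7)
        assert space.coordinates.shape[1] == 7
        np.testing.assert_allclose(space.coordinates.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(space.coordinates.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_pcoa_reduction_preserves_distances_when_full_dim(self, study):
        """PCoA to the full dimensionality is an isometry: FRic unchanged."""
        from germfilter.fd import _pcoa_coordinates

        profiles, _ = study
        space = build_trait_space(profiles, m=7)
        reduced = _pcoa_coordinates(space.coordinates, 7)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            np.sort(pdist(reduced)), np.sort(pdist(space.coordinates)), atol=1e-8
        )

    def test_fd_all_covers_every_quadrat(self, study):
        profiles, quadrats = study
        space = build_trait_space(profiles, "auto", quadrats)
        results = fd_all(space, quadrats)
        assert len(results) == len(quadrats)
        for r in results:
            if r.feve is not None:
                assert 0.0 <= r.feve <= 1.0
            if r.fdiv is not None:
                assert 0.0 <= r.fdiv <= 1.0
            if r.fric is not None:
                assert r.fric >= 0.0
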