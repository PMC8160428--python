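import numpy as np
import pytest

from germfilter import SimulationConfig
from germfilter.types import (
    GerminationTrial,
    StorageTreatment,
    TemperatureCondition,
)


def make_trial(
    species="spA",
    condition=TemperatureCondition.T15,
    storage=StorageTreatment.DRY_WARM,
    replicate=1,
    n_sown=50,
    days_counts=(),
    duration=60,
):
    """Build a trial from sparse (day, count) pairs."""
    daily = [0] * duration
    for day, count in days_counts:
        daily[day - 1] = count
    return GerminationTrial(
        species_id=species,
        condition=condition,
        storage=storage,
        replicate_id=replicate,
        n_sown=n_sown,
        daily_counts=tuple(daily),
    )


def random_trials_for_species(rng, species, duration=20, n_sown=30):
    """One full condition grid of random trials for one species."""
    from germfilter.simulate import TRIAL_GRID

    trials = []
    for condition, storage in TRIAL_GRID:
        for rep in (1, 2, 3):
            total = int(rng.integers(0, n_sown + 1))
            daily = np.zeros(duration, dtype=int)
            if total:
                days = rng.integers(1, duration + 1, total)
                daily = np.bincount(days - 1, minlength=duration)
            trials.append(
                GerminationTrial(
                    species_id=species,
                    condition=condition,
                    storage=storage,
                    replicate_id=rep,
                    n_sown=n_sown,
                    daily_counts=tuple(int(c) for c in daily),
                )
            )
    return trials


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_sim_config():
    """A scaled-down simulated study (fast enough for per-test use)."""
    return SimulationConfig(
        n_species=15,
        n_blocks=3,
        quadrat_total_individuals=200.0,
        duration_days=30,
        rng_seed=11,
    )
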