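"""Synthetic germination trials and vegetation quadrats.

The generator emulates the study design the analysis assumes: a pool of
species (default 63) whose germination follows a Gaussian thermal-response
curve, laboratory trials at five constant temperatures plus an alternating
5/25 degC regime (with a wet-cold storage contrast run at the alternating
regime), and a blocked nitrogen-addition field experiment (default 5 blocks x
4 doses, one quadrat each).

Species' fertilization responses can be coupled to their germination traits
(e.g. thermal-niche breadth), so inference stages can be validated by
parameter recovery: the coupling fixes the true direction and ordering that
the downstream regressions should detect.

All randomness flows from one root seed through named substreams, so adding a
stage never perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .types import (
    CONSTANT_TEMPERATURES,
    GerminationTrial,
    NitrogenLevel,
    StorageTreatment,
    TemperatureCondition,
    ValidationError,
    VegetationQuadrat,
)

__all__ = [
    "SpeciesSimParams",
    "SimulationConfig",
    "draw_species_pool",
    "true_germination_probability",
    "true_btn",
    "simulate_trials",
    "simulate_quadrats",
    "pool_to_frame",
]

#: Trait names accepted as coupling keys, i.e. species attributes that may
#: drive the fertilization response.
COUPLING_TRAITS = ("GP_low_T", "BTN", "alt_effect", "coldstrat_effect")

_P_FLOOR = 1e-9  # germination probabilities are clamped to (floor, 1 - floor)


@dataclass(frozen=True)
class SpeciesSimParams:
    """Ground-truth parameters of one simulated species.

    The thermal response is Gaussian: p(T) = p_max * exp(-(T - t_opt)^2 /
    (2 t_sd^2)). ``alt_effect`` and ``coldstrat_effect`` shift the
    germination log-odds under the alternating regime and after wet-cold
    storage; ``timing_hazard`` is the daily germination hazard of a seed that
    will germinate; ``n_response_slope`` is the change in log expected
    abundance over the full fertilization dose range (control -> top dose).
    """

    species_id: str
    p_max: float
    t_opt: float
    t_sd: float
    alt_effect: float
    coldstrat_effect: float
    timing_hazard: float
    base_log_abundance: float
    n_response_slope: float

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ValidationError(f"{self.species_id}: p_max must be in (0, 1]")
        if self.t_sd <= 0:
            raise ValidationError(f"{self.species_id}: t_sd must be positive")
        if not 0 < self.timing_hazard <= 1:
            raise ValidationError(f"{self.species_id}: timing_hazard must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Study-design constants and generator couplings.

    Defaults mirror the emulated field/lab design: 63 species, 5 blocks x 4
    nitrogen doses (0/5/10/20 g N m^-2 yr^-1) with one 50 x 50 cm quadrat
    per plot, and germination tests of 3 replicates x 50 seeds for 60 days.
    ``coupling`` maps a trait name to the effect (per SD of the trait) on the
    species' fertilization response slope; ``noise_sd`` is the residual SD of
    that slope; ``block_sd`` the SD of species-by-block log-abundance noise.
    """

    n_species: int = 63
    n_blocks: int = 5
    n_levels: Sequence[float] = (0.0, 5.0, 10.0, 20.0)
    replicates: int = 3
    seeds_per_replicate: int = 50
    duration_days: int = 60
    quadrat_total_individuals: float = 400.0
    coupling: dict[str, float] = field(default_factory=dict)
    block_sd: float = 0.3
    noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_species", self.n_species),
            ("n_blocks", self.n_blocks),
            ("replicates", self.replicates),
            ("seeds_per_replicate", self.seeds_per_replicate),
            ("duration_days", self.duration_days),
            ("quadrat_total_individuals", self.quadrat_total_individuals),
        ):
            if value <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.block_sd < 0 or self.noise_sd < 0:
            raise ValidationError("block_sd and noise_sd must be non-negative")
        unknown = set(self.coupling) - set(COUPLING_TRAITS)
        if unknown:
            raise ValidationError(
                f"unknown coupling traits {sorted(unknown)}; valid: {COUPLING_TRAITS}"
            )
        if tuple(self.n_levels) != tuple(sorted(self.n_levels)):
            raise ValidationError("n_levels doses must be increasing")
        if len(self.n_levels) != len(NitrogenLevel):
            raise ValidationError(f"expected {len(NitrogenLevel)} dose levels")

    def substream(self, stage: str) -> np.random.Generator:
        """Named child RNG stream, independent across stages."""
        stage_key = int.from_bytes(stage.encode("utf-8"), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.rng_seed, stage_key)))


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _clamp(p):
    return np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)


def true_germination_probability(
    sp: SpeciesSimParams,
    condition: TemperatureCondition,
    storage: StorageTreatment = StorageTreatment.DRY_WARM,
) -> float:
    """Ground-truth germination probability for one condition/storage combo.

    Constant temperature T: p = p_max * exp(-(T - t_opt)^2 / (2 t_sd^2)).
    Alternating regime: the 15 degC probability shifted by ``alt_effect`` on
    the logit scale. Wet-cold storage adds ``coldstrat_effect`` on the logit
    scale. The result is clamped away from exactly 0/1 before sampling.
    """
    if condition.is_constant:
        temp = condition.nominal_mean_celsius
        p = sp.p_max * np.exp(-((temp - sp.t_opt) ** 2) / (2.0 * sp.t_sd**2))
    else:
        p15 = sp.p_max * np.exp(-((15.0 - sp.t_opt) ** 2) / (2.0 * sp.t_sd**2))
        p = _expit(_logit(_clamp(p15)) + sp.alt_effect)
    if storage is StorageTreatment.DRY_WARM_WET_COLD:
        p = _expit(_logit(_clamp(p)) + sp.coldstrat_effect)
    return float(_clamp(p))


def true_btn(sp: SpeciesSimParams) -> float:
    """Closed-form thermal-niche breadth implied by the Gaussian curve.

    With g_j the true germination probability at the five constant
    temperatures, BTN = mean_j(g_j / max_j g_j); p_max cancels, so BTN
    depends on (t_opt, t_sd) only.
    """
    temps = np.array([c.nominal_mean_celsius for c in CONSTANT_TEMPERATURES])
    g = np.exp(-((temps - sp.t_opt) ** 2) / (2.0 * sp.t_sd**2))
    return float(np.mean(g / g.max()))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def draw_species_pool(config: SimulationConfig) -> list[SpeciesSimParams]:
    """Draw the species pool from the documented trait distributions.

    t_opt ~ U(5, 25); t_sd ~ LogNormal(log 6, 0.4); p_max ~ Beta(4, 2);
    alt_effect ~ N(0.5, 0.7); coldstrat_effect ~ N(0.3, 0.7);
    timing_hazard ~ U(0.03, 0.5); base_log_abundance ~ N(0, 1).
    The fertilization-response slope is a linear combination of the
    (standardized) coupled traits plus N(0, noise_sd) residual noise.
    """
    rng = config.substream("species_pool")
    n = config.n_species
    t_opt = rng.uniform(5.0, 25.0, n)
    t_sd = rng.lognormal(np.log(6.0), 0.4, n)
    p_max = rng.beta(4.0, 2.0, n)
    alt_effect = rng.normal(0.5, 0.7, n)
    coldstrat_effect = rng.normal(0.3, 0.7, n)
    timing_hazard = rng.uniform(0.03, 0.5, n)
    base_log_abundance = rng.normal(0.0, 1.0, n)

    width = max(2, len(str(n)))
    ids = [f"sp{i + 1:0{width}d}" for i in range(n)]
    pool = [
        SpeciesSimParams(
            species_id=ids[i],
            p_max=float(p_max[i]),
            t_opt=float(t_opt[i]),
            t_sd=float(t_sd[i]),
            alt_effect=float(alt_effect[i]),
            coldstrat_effect=float(coldstrat_effect[i]),
            timing_hazard=float(timing_hazard[i]),
            base_log_abundance=float(base_log_abundance[i]),
            n_response_slope=0.0,
        )
        for i in range(n)
    ]

    trait_values = {
        "GP_low_T": np.array(
            [true_germination_probability(sp, TemperatureCondition.T5) for sp in pool]
        ),
        "BTN": np.array([true_btn(sp) for sp in pool]),
        "alt_effect": alt_effect,
        "coldstrat_effect": coldstrat_effect,
    }
    slope = np.zeros(n)
    for trait, gamma in sorted(config.coupling.items()):
        slope += gamma * _standardize(trait_values[trait])
    if config.noise_sd > 0:
        slope += rng.normal(0.0, config.noise_sd, n)
    return [replace(sp, n_response_slope=float(slope[i])) for i, sp in enumerate(pool)]


#: Condition/storage grid of the two germination experiments: six regimes
#: after dry-warm storage, plus the alternating regime after wet-cold storage
#: (the storage contrast consumed by the wet-cold response index).
TRIAL_GRID: tuple[tuple[TemperatureCondition, StorageTreatment], ...] = tuple(
    [(c, StorageTreatment.DRY_WARM) for c in TemperatureCondition]
    + [(TemperatureCondition.ALT_5_25, StorageTreatment.DRY_WARM_WET_COLD)]
)


def simulate_trials(
    pool: Iterable[SpeciesSimParams], config: SimulationConfig
) -> list[GerminationTrial]:
    """Simulate the germination experiments over the full condition grid.

    Per replicate dish the number of germinating seeds is Binomial(n, p) at
    the species' true probability; each germinating seed's day is Geometric
    (timing_hazard). Seeds drawn beyond the trial duration are recorded as
    not germinated, so slow germinators are right-censored exactly as in a
    finite trial.
    """
    rng = config.substream("trials")
    n_seeds = config.seeds_per_replicate
    duration = config.duration_days
    trials: list[GerminationTrial] = []
    for sp in pool:
        for condition, storage in TRIAL_GRID:
            p = true_germination_probability(sp, condition, storage)
            for rep in range(1, config.replicates + 1):
                k = int(rng.binomial(n_seeds, p))
                daily = np.zeros(duration, dtype=np.int64)
                if k > 0:
                    days = rng.geometric(sp.timing_hazard, k)
                    days = days[days <= duration]  # censored at trial end
                    if days.size:
                        daily = np.bincount(days - 1, minlength=duration)
                trials.append(
                    GerminationTrial(
                        species_id=sp.species_id,
                        condition=condition,
                        storage=storage,
                        replicate_id=rep,
                        n_sown=n_seeds,
                        daily_counts=tuple(int(c) for c in daily),
                    )
                )
    return trials


def simulate_quadrats(
    pool: Sequence[SpeciesSimParams], config: SimulationConfig
) -> list[VegetationQuadrat]:
    """Simulate the blocked fertilization experiment's vegetation counts.

    Expected relative abundance of species i in block b at dose d is
    proportional to exp(base_i + slope_i * d/d_max + eps_{i,b}), with
    eps_{i,b} ~ N(0, block_sd) shared across doses within a block (the block
    random effect). Counts are Multinomial with a Poisson total per quadrat.
    """
    rng = config.substream("quadrats")
    n = len(pool)
    base = np.array([sp.base_log_abundance for sp in pool])
    slope = np.array([sp.n_response_slope for sp in pool])
    d_max = max(config.n_levels)
    block_ids = [f"b{b + 1}" for b in range(config.n_blocks)]
    levels = list(NitrogenLevel)

    quadrats: list[VegetationQuadrat] = []
    for block in block_ids:
        block_eff = rng.normal(0.0, config.block_sd, n) if config.block_sd > 0 else np.zeros(n)
        for level, dose in zip(levels, config.n_levels):
            eta = base + slope * (dose / d_max) + block_eff
            props = np.exp(eta - eta.max())
            props /= props.sum()
            total = int(rng.poisson(config.quadrat_total_individuals))
            while total <= 0:  # a quadrat always holds at least one plant
                total = int(rng.poisson(config.quadrat_total_individuals))
            counts = rng.multinomial(total, props)
            if counts.sum() == 0 or counts.max() == 0:  # defensive; total > 0
                counts[int(np.argmax(props))] = 1
            quadrats.append(
                VegetationQuadrat(
                    block_id=block,
                    n_level=level,
                    species_counts={
                        pool[i].species_id: int(counts[i]) for i in range(n) if counts[i] > 0
                    },
                )
            )
    return quadrats


def pool_to_frame(pool: Sequence[SpeciesSimParams]):
    """Ground-truth table (one row per species) for parameter-recovery tests."""
    import pandas as pd

    rows = []
    for sp in pool:
        rows.append(
            {
                "species_id": sp.species_id,
                "p_max": sp.p_max,
                "t_opt": sp.t_opt,
                "t_sd": sp.t_sd,
                "alt_effect": sp.alt_effect,
                "coldstrat_effect": sp.coldstrat_effect,
                "timing_hazard": sp.timing_hazard,
                "base_log_abundance": sp.base_log_abundance,
                "n_response_slope": sp.n_response_slope,
                "true_btn": true_btn(sp),
            }
        )
    return pd.DataFrame(rows)
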