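"""Shared domain types for the germination-trait / community-assembly pipeline.

The experimental unit of the germination trials is one species incubated under
one temperature condition after one storage treatment, replicated in Petri
dishes; the unit of the vegetation survey is one quadrat (block x nitrogen
level) with individual counts per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TemperatureCondition",
    "StorageTreatment",
    "NitrogenLevel",
    "GerminationTrial",
    "VegetationQuadrat",
    "AnalysisConfig",
    "CONSTANT_TEMPERATURES",
    "N_LEVEL_DOSES",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input table or record violates a structural invariant."""


class TemperatureCondition(Enum):
    """Incubation regime of a germination trial.

    Five constant temperatures span the field's germination-season range and
    define the temperature-niche axis (R = 5); ``ALT_5_25`` is a 5/25 degC
    (12 h / 12 h) alternating regime whose nominal daily mean is 15 degC, the
    comparison point for the alternating-temperature response index.
    """

    T5 = 5.0
    T10 = 10.0
    T15 = 15.0
    T20 = 20.0
    T25 = 25.0
    ALT_5_25 = 15.0001  # distinct enum value; nominal mean given by property

    @property
    def nominal_mean_celsius(self) -> float:
        if self is TemperatureCondition.ALT_5_25:
            return 15.0
        return float(self.value)

    @property
    def is_constant(self) -> bool:
        return self is not TemperatureCondition.ALT_5_25


#: The constant members defining the niche axis, in increasing order.
CONSTANT_TEMPERATURES: tuple[TemperatureCondition, ...] = (
    TemperatureCondition.T5,
    TemperatureCondition.T10,
    TemperatureCondition.T15,
    TemperatureCondition.T20,
    TemperatureCondition.T25,
)


class StorageTreatment(Enum):
    """Pre-incubation seed storage: dry-warm after-ripening, optionally
    followed by 40 days of moist chilling (cold stratification)."""

    DRY_WARM = "DRY_WARM"
    DRY_WARM_WET_COLD = "DRY_WARM_WET_COLD"


class NitrogenLevel(Enum):
    """Fertilization treatment, in g N m^-2 yr^-1."""

    N0 = 0.0
    N1 = 5.0
    N2 = 10.0
    N3 = 20.0

    @property
    def dose(self) -> float:
        return float(self.value)


#: Dose (g N m^-2 yr^-1) per treatment label, in factor order.
N_LEVEL_DOSES: dict[str, float] = {lv.name: lv.dose for lv in NitrogenLevel}


@dataclass(frozen=True)
class GerminationTrial:
    """Raw daily germination counts for one replicate dish.

    ``daily_counts[d]`` is the number of seeds whose radicle first emerged on
    day ``d + 1`` after sowing (day indexing is 1-based: day 1 is the first
    daily check). Seeds never germinating within the trial simply do not
    appear, so ``sum(daily_counts) <= n_sown``.
    """

    species_id: str
    condition: TemperatureCondition
    storage: StorageTreatment
    replicate_id: int
    n_sown: int
    daily_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_sown <= 0:
            raise ValidationError(f"trial {self.key}: n_sown must be positive")
        if self.replicate_id < 1:
            raise ValidationError(f"trial {self.key}: replicate_id must be >= 1")
        if any(c < 0 for c in self.daily_counts):
            raise ValidationError(f"trial {self.key}: negative daily count")
        if sum(self.daily_counts) > self.n_sown:
            raise ValidationError(
                f"trial {self.key}: germinated total {sum(self.daily_counts)} "
                f"exceeds seeds sown {self.n_sown}"
            )

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.species_id, self.condition.name, self.storage.name, self.replicate_id)

    @property
    def total_germinated(self) -> int:
        return int(sum(self.daily_counts))

    def counts_array(self) -> np.ndarray:
        return np.asarray(self.daily_counts, dtype=np.int64)


@dataclass(frozen=True)
class VegetationQuadrat:
    """Individual counts per species in one 50 x 50 cm quadrat."""

    block_id: str
    n_level: NitrogenLevel
    species_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.species_counts.values()):
            raise ValidationError(
                f"quadrat ({self.block_id}, {self.n_level.name}): negative count"
            )
        if not any(c > 0 for c in self.species_counts.values()):
            raise ValidationError(
                f"quadrat ({self.block_id}, {self.n_level.name}): no positive count"
            )

    @property
    def total_individuals(self) -> int:
        return int(sum(self.species_counts.values()))


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages (not of the data generator).

    boundary_epsilon is the tolerance used to detect +-1 boundary response
    values before beta regression; fd_axes fixes the trait-space
    dimensionality or lets it adapt to the poorest community ("auto").
    """

    trial_duration_days: int = 60
    niche_temperatures: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0)
    boundary_epsilon: float = 1e-9
    fd_axes: int | str = "auto"
    rng_seed: int = 0
    significance_level: float = 0.05
    gp_pooling: str = "pooled"   # "pooled" (ratio of summed counts) or "mean"
    gr_pooling: str = "mean"     # "mean" (per-replicate average) or "pooled"
    rf_pooling: str = "pooled"   # "pooled" across blocks or "per_block" mean

    def __post_init__(self) -> None:
        if self.trial_duration_days <= 0:
            raise ValidationError("trial_duration_days must be positive")
        if not 0 < self.significance_level < 1:
            raise ValidationError("significance_level must lie in (0, 1)")
        if self.boundary_epsilon <= 0:
            raise ValidationError("boundary_epsilon must be positive")
        if self.fd_axes != "auto" and int(self.fd_axes) < 1:
            raise ValidationError("fd_axes must be >= 1 or 'auto'")
        if self.gp_pooling not in ("pooled", "mean"):
            raise ValidationError("gp_pooling must be 'pooled' or 'mean'")
        if self.gr_pooling not in ("mean", "pooled"):
            raise ValidationError("gr_pooling must be 'mean' or 'pooled'")
        if self.rf_pooling not in ("pooled", "per_block"):
            raise ValidationError("rf_pooling must be 'pooled' or 'per_block'")
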