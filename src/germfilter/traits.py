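"""Species-level germination indices and temperature-niche metrics.

For each species the germination trials yield, per incubation condition, a
germination percentage GP (final fraction of sown seeds germinated) and a
germination rate GR (a Maguire-type speed index, Sum_i G_i / (n * i), which
equals 1 when every seed germinates on day 1). Two normalized contrasts
summarize regime responses: R_5/25 compares the alternating 5/25 degC regime
with constant 15 degC, and R_wc compares wet-cold-stratified with dry-stored
seeds. The temperature niche over the R = 5 constant temperatures is
described by the occupation index O_j = g_j / g_max, its normalized profile
P_j = O_j / Sum O, and the niche breadth BTN = mean_j O_j in [1/R, 1].

Indices that are undefined (no germination anywhere, or a condition missing
from the data) are carried as explicit missing values with a reason code,
never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    CONSTANT_TEMPERATURES,
    AnalysisConfig,
    GerminationTrial,
    StorageTreatment,
    TemperatureCondition,
    ValidationError,
)

__all__ = [
    "SpeciesGermProfile",
    "germination_percentage",
    "germination_rate",
    "response_alternating",
    "response_wet_cold",
    "niche_metrics",
    "build_profiles",
    "profiles_to_frame",
    "frame_to_profiles",
    "TRAIT_VARIABLES",
]

#: Reason codes attached to undefined indices.
NO_GERMINATION = "no_germination"
MISSING_CONDITION = "missing_condition"

_COND_ORDER = [c.name for c in TemperatureCondition]


@dataclass
class SpeciesGermProfile:
    """All derived germination indices of one species.

    Maps are keyed by condition name (gp/gr) or by constant temperature in
    degC (occupation/proportion_niche); missing entries are ``None`` with the
    reason recorded in ``reasons``.
    """

    species_id: str
    gp: dict[str, float | None] = field(default_factory=dict)
    gr: dict[str, float | None] = field(default_factory=dict)
    gp_wc: float | None = None
    r_alt: float | None = None
    r_wc: float | None = None
    occupation: dict[float, float | None] = field(default_factory=dict)
    proportion_niche: dict[float, float | None] = field(default_factory=dict)
    btn: float | None = None
    reasons: dict[str, str] = field(default_factory=dict)

    def trait_value(self, name: str) -> float | None:
        """Look up a named trait variable (e.g. ``GP_T5``, ``O_10``, ``BTN``)."""
        if name == "BTN":
            return self.btn
        if name == "R_5_25":
            return self.r_alt
        if name == "R_wc":
            return self.r_wc
        if name == "GP_wc":
            return self.gp_wc
        kind, _, key = name.partition("_")
        if kind == "GP":
            return self.gp.get(key)
        if kind == "GR":
            return self.gr.get(key)
        if kind == "O":
            return self.occupation.get(float(key))
        if kind == "P":
            return self.proportion_niche.get(float(key))
        raise KeyError(name)


def _check_same_unit(trials: Sequence[GerminationTrial]) -> None:
    if not trials:
        raise ValidationError("no trials supplied")
    keys = {(t.species_id, t.condition, t.storage) for t in trials}
    if len(keys) > 1:
        raise ValidationError(f"trials mix species/condition/storage: {sorted(map(str, keys))}")


def germination_percentage(
    trials: Sequence[GerminationTrial], pooling: str = "pooled"
) -> float:
    """Final germinated fraction, GP = G_fin / n, over replicate dishes.

    ``pooled`` (default) is the ratio of summed counts over summed seeds —
    exact for binomial sampling; ``mean`` averages per-replicate fractions.
    """
    _check_same_unit(trials)
    if pooling == "pooled":
        return sum(t.total_germinated for t in trials) / sum(t.n_sown for t in trials)
    if pooling == "mean":
        return float(np.mean([t.total_germinated / t.n_sown for t in trials]))
    raise ValueError(f"unknown pooling {pooling!r}")


def _gr_one(trial: GerminationTrial) -> float:
    counts = trial.counts_array()
    days = np.arange(1, counts.size + 1, dtype=float)
    return float(np.sum(counts / days) / trial.n_sown)


def germination_rate(trials: Sequence[GerminationTrial], pooling: str = "mean") -> float:
    """Speed-weighted germination index GR = (1/n) Sum_i G_i / i.

    Bounded by GP (each day's term G_i/i <= G_i) and equal to 1 only when all
    seeds germinate on day 1. ``mean`` (default) averages per-replicate
    values; ``pooled`` computes the index on summed daily counts.
    """
    _check_same_unit(trials)
    if pooling == "mean":
        return float(np.mean([_gr_one(t) for t in trials]))
    if pooling == "pooled":
        counts = np.sum([t.counts_array() for t in trials], axis=0)
        days = np.arange(1, counts.size + 1, dtype=float)
        return float(np.sum(counts / days) / sum(t.n_sown for t in trials))
    raise ValueError(f"unknown pooling {pooling!r}")


def response_alternating(gp_alt: float, gp_15: float) -> float | None:
    """Alternating-temperature response R_5/25 = (GP_alt - GP_15)/(GP_alt + GP_15).

    Positive when fluctuating temperature promotes germination (a vegetation
    gap cue). Undefined (None) when both percentages are zero.
    """
    total = gp_alt + gp_15
    if total == 0:
        return None
    return (gp_alt - gp_15) / total


def response_wet_cold(gp_wc: float, gp_dr: float) -> float | None:
    """Wet-cold storage response R_wc = (GP_wc - GP_dr)/(GP_wc + GP_dr).

    Positive when cold stratification promotes germination (a dormancy
    syndrome). Undefined when both percentages are zero.
    """
    total = gp_wc + gp_dr
    if total == 0:
        return None
    return (gp_wc - gp_dr) / total


def niche_metrics(
    gp_by_temperature: Mapping[float, float],
    niche_temperatures: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0),
) -> tuple[dict[float, float] | None, dict[float, float] | None, float | None]:
    """Occupation O_j, niche proportion P_j and breadth BTN over R temperatures.

    O_j = g_j / g_max; P_j = O_j / Sum_k O_k; BTN = (1/R) Sum_j O_j. All three
    are undefined when no germination occurred at any constant temperature.
    """
    temps = tuple(niche_temperatures)
    if set(gp_by_temperature) != set(temps):
        raise ValidationError(
            f"expected GPs at temperatures {temps}, got {sorted(gp_by_temperature)}"
        )
    g = np.array([gp_by_temperature[t] for t in temps], dtype=float)
    if np.any(g < 0):
        raise ValidationError("germination percentages must be non-negative")
    g_max = g.max()
    if g_max == 0:
        return None, None, None
    occ = g / g_max
    prop = occ / occ.sum()
    btn = float(occ.mean())
    return (
        {t: float(o) for t, o in zip(temps, occ)},
        {t: float(p) for t, p in zip(temps, prop)},
        btn,
    )


def build_profiles(
    trials: Iterable[GerminationTrial], config: AnalysisConfig | None = None
) -> list[SpeciesGermProfile]:
    """Derive one :class:`SpeciesGermProfile` per species from raw trials.

    GP/GR are computed per condition from the dry-warm trials; the wet-cold
    GP comes from the alternating-regime trials after stratification. Missing
    conditions leave the dependent indices undefined with reason
    ``missing_condition``; an all-zero niche leaves O/P/BTN (and, if both
    sides are zero, the R contrasts) undefined with reason ``no_germination``.
    """
    config = config or AnalysisConfig()
    by_species: dict[str, dict[tuple[TemperatureCondition, StorageTreatment], list]] = {}
    for t in trials:
        by_species.setdefault(t.species_id, {}).setdefault((t.condition, t.storage), []).append(t)

    profiles = []
    for species in sorted(by_species):
        groups = by_species[species]
        prof = SpeciesGermProfile(species_id=species)

        for cond in TemperatureCondition:
            reps = groups.get((cond, StorageTreatment.DRY_WARM))
            if reps:
                prof.gp[cond.name] = germination_percentage(reps, config.gp_pooling)
                prof.gr[cond.name] = germination_rate(reps, config.gr_pooling)
            else:
                prof.gp[cond.name] = None
                prof.gr[cond.name] = None
                prof.reasons[f"GP_{cond.name}"] = MISSING_CONDITION
                prof.reasons[f"GR_{cond.name}"] = MISSING_CONDITION

        wc_reps = groups.get((TemperatureCondition.ALT_5_25, StorageTreatment.DRY_WARM_WET_COLD))
        if wc_reps:
            prof.gp_wc = germination_percentage(wc_reps, config.gp_pooling)
        else:
            prof.reasons["GP_wc"] = MISSING_CONDITION

        gp_alt = prof.gp[TemperatureCondition.ALT_5_25.name]
        gp_15 = prof.gp[TemperatureCondition.T15.name]
        if gp_alt is None or gp_15 is None:
            prof.reasons["R_5_25"] = MISSING_CONDITION
        else:
            prof.r_alt = response_alternating(gp_alt, gp_15)
            if prof.r_alt is None:
                prof.reasons["R_5_25"] = NO_GERMINATION

        # The storage contrast is measured at the same (alternating)
        # incubation regime for both storage histories.
        if prof.gp_wc is None or gp_alt is None:
            prof.reasons["R_wc"] = MISSING_CONDITION
        else:
            prof.r_wc = response_wet_cold(prof.gp_wc, gp_alt)
            if prof.r_wc is None:
                prof.reasons["R_wc"] = NO_GERMINATION

        temps = tuple(config.niche_temperatures)
        const_gps = {
            c.nominal_mean_celsius: prof.gp[c.name]
            for c in CONSTANT_TEMPERATURES
            if c.nominal_mean_celsius in temps
        }
        if any(v is None for v in const_gps.values()) or set(const_gps) != set(temps):
            prof.occupation = {t: None for t in temps}
            prof.proportion_niche = {t: None for t in temps}
            prof.reasons["BTN"] = MISSING_CONDITION
        else:
            occ, prop, btn = niche_metrics(const_gps, temps)
            if btn is None:
                prof.occupation = {t: None for t in temps}
                prof.proportion_niche = {t: None for t in temps}
                prof.reasons["BTN"] = NO_GERMINATION
            else:
                prof.occupation = occ
                prof.proportion_niche = prop
                prof.btn = btn
        profiles.append(prof)
    return profiles


def _temp_label(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def _trait_variables(niche_temperatures: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0)):
    names = [f"GP_{c.name}" for c in TemperatureCondition]
    names += [f"GR_{c.name}" for c in TemperatureCondition]
    names += ["GP_wc", "R_5_25", "R_wc"]
    names += [f"O_{_temp_label(t)}" for t in niche_temperatures]
    names += [f"P_{_temp_label(t)}" for t in niche_temperatures]
    names += ["BTN"]
    return names


#: Column order of the per-species profile table.
TRAIT_VARIABLES: list[str] = _trait_variables()


def profiles_to_frame(profiles: Sequence[SpeciesGermProfile]) -> pd.DataFrame:
    """Tidy one-row-per-species table of all indices (NaN where undefined)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"species_id": p.species_id}
        for c in TemperatureCondition:
            row[f"GP_{c.name}"] = p.gp.get(c.name)
            row[f"GR_{c.name}"] = p.gr.get(c.name)
        row["GP_wc"] = p.gp_wc
        row["R_5_25"] = p.r_alt
        row["R_wc"] = p.r_wc
        for t in sorted(p.occupation):
            row[f"O_{_temp_label(t)}"] = p.occupation[t]
        for t in sorted(p.proportion_niche):
            row[f"P_{_temp_label(t)}"] = p.proportion_niche[t]
        row["BTN"] = p.btn
        row["undefined_reasons"] = ";".join(
            f"{k}={v}" for k, v in sorted(p.reasons.items())
        )
        rows.append(row)
    columns = ["species_id"] + TRAIT_VARIABLES + ["undefined_reasons"]
    return pd.DataFrame(rows, columns=columns)


def frame_to_profiles(df: pd.DataFrame) -> list[SpeciesGermProfile]:
    """Inverse of :func:`profiles_to_frame` (reasons parsed back verbatim)."""
    profiles = []
    temps = [5.0, 10.0, 15.0, 20.0, 25.0]

    def val(row, name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    for _, row in df.iterrows():
        rowd = row.to_dict()
        p = SpeciesGermProfile(species_id=str(rowd["species_id"]))
        for c in TemperatureCondition:
            p.gp[c.name] = val(rowd, f"GP_{c.name}")
            p.gr[c.name] = val(rowd, f"GR_{c.name}")
        p.gp_wc = val(rowd, "GP_wc")
        p.r_alt = val(rowd, "R_5_25")
        p.r_wc = val(rowd, "R_wc")
        p.occupation = {t: val(rowd, f"O_{_temp_label(t)}") for t in temps}
        p.proportion_niche = {t: val(rowd, f"P_{_temp_label(t)}") for t in temps}
        p.btn = val(rowd, "BTN")
        reasons = rowd.get("undefined_reasons")
        if isinstance(reasons, str) and reasons:
            p.reasons = dict(item.split("=", 1) for item in reasons.split(";"))
        profiles.append(p)
    return profiles
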