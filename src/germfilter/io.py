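"""CSV readers/writers for trial and quadrat tables and tidy results.

Trial files are long format: one row per (species, condition, storage,
replicate, day) with a positive count; days not listed germinated zero seeds.
All files are RFC-4180 CSV, UTF-8, "." decimal. Floats are written at 10
significant digits so written tables round-trip.
"""

from __future__ import annotations

import os
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AnalysisConfig,
    GerminationTrial,
    NitrogenLevel,
    StorageTreatment,
    TemperatureCondition,
    ValidationError,
    VegetationQuadrat,
)

__all__ = ["read_trials", "read_quadrats", "write_table", "read_table"]

_TRIAL_COLUMNS = ["species_id", "condition", "storage", "replicate", "n_sown", "day", "count"]
_QUADRAT_COLUMNS = ["block", "n_level", "species_id", "count"]


class ParseError(ValidationError):
    """A malformed row in an input table."""


def _enum_lookup(enum_cls, label: str, row: int, what: str):
    try:
        return enum_cls[str(label).strip()]
    except KeyError:
        valid = ", ".join(m.name for m in enum_cls)
        raise ParseError(f"row {row}: unknown {what} {label!r} (expected one of {valid})")


def read_trials(path: str, config: AnalysisConfig | None = None) -> list[GerminationTrial]:
    """Read germination trials from a long-format CSV.

    Missing (trial, day) rows imply zero seeds germinated that day. Rows with
    a day outside 1..trial_duration_days, or trials whose summed counts
    exceed seeds sown, raise ``ValidationError`` naming the offender.
    """
    config = config or AnalysisConfig()
    duration = config.trial_duration_days
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"trial file missing columns: {missing}")

    grouped: dict[tuple, dict] = {}
    for idx, rec in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        try:
            species = str(rec.species_id).strip()
            condition = _enum_lookup(TemperatureCondition, rec.condition, idx, "condition")
            storage = _enum_lookup(StorageTreatment, rec.storage, idx, "storage")
            replicate = int(rec.replicate)
            n_sown = int(rec.n_sown)
            day = int(rec.day)
            count = int(rec.count)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {idx}: malformed value ({exc})") from exc
        if not 1 <= day <= duration:
            raise ValidationError(
                f"row {idx}: day {day} outside 1..{duration} for species {species}"
            )
        if count < 0:
            raise ValidationError(f"row {idx}: negative count")
        key = (species, condition, storage, replicate)
        entry = grouped.setdefault(key, {"n_sown": n_sown, "counts": defaultdict(int)})
        if entry["n_sown"] != n_sown:
            raise ValidationError(
                f"row {idx}: inconsistent n_sown for trial {key} "
                f"({entry['n_sown']} vs {n_sown})"
            )
        entry["counts"][day] += count

    trials = []
    for (species, condition, storage, replicate), entry in grouped.items():
        daily = [0] * duration
        for day, count in entry["counts"].items():
            daily[day - 1] = count
        trials.append(
            GerminationTrial(
                species_id=species,
                condition=condition,
                storage=storage,
                replicate_id=replicate,
                n_sown=entry["n_sown"],
                daily_counts=tuple(daily),
            )
        )
    trials.sort(key=lambda t: t.key)
    return trials


def read_quadrats(path: str) -> list[VegetationQuadrat]:
    """Read vegetation quadrats: one record per (block, n_level).

    Duplicate (block, n_level, species) rows are an error, as is an unknown
    nitrogen-level label.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _QUADRAT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"quadrat file missing columns: {missing}")

    counts: dict[tuple[str, NitrogenLevel], dict[str, int]] = {}
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        block = str(rec.block).strip()
        level = _enum_lookup(NitrogenLevel, rec.n_level, idx, "n_level")
        species = str(rec.species_id).strip()
        try:
            count = int(rec.count)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {idx}: malformed count ({exc})") from exc
        quadrat = counts.setdefault((block, level), {})
        if species in quadrat:
            raise ValidationError(
                f"row {idx}: duplicate species {species!r} in quadrat ({block}, {level.name})"
            )
        quadrat[species] = count

    quadrats = [
        VegetationQuadrat(block_id=block, n_level=level, species_counts=dict(sorted(sp.items())))
        for (block, level), sp in counts.items()
    ]
    quadrats.sort(key=lambda q: (q.block_id, q.n_level.name))
    return quadrats


def write_table(records: pd.DataFrame | Iterable[dict], path: str,
                columns: Sequence[str] | None = None) -> None:
    """Write a tidy result table as CSV with stable column order.

    Floats are formatted at 10 significant digits; missing values are empty
    cells. Parent directory must exist.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=columns)
    elif columns is not None:
        records = records[list(columns)]
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise IOError(f"directory does not exist: {directory}")
    records.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_table(path: str) -> pd.DataFrame:
    """Read back a tidy result table written by :func:`write_table`."""
    return pd.read_csv(path)
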