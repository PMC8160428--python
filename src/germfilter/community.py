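"""Relative abundance, the fertilization-response index and community-weighted
means.

The fertilization response of species i is the normalized change of its
relative abundance between the top nitrogen dose and the control,
R_f = (RA_N3 - RA_N0) / (RA_N3 + RA_N0): +1 means present only under high N,
-1 only in the control. Community-weighted means (CWM) average a trait over a
quadrat's species weighted by relative abundance; species whose trait is
undefined are excluded with the weights renormalized, and the abundance share
they would have carried is reported as coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import NitrogenLevel, ValidationError, VegetationQuadrat
from .traits import SpeciesGermProfile

__all__ = [
    "SpeciesAbundanceResponse",
    "CommunityTraitSummary",
    "relative_abundance",
    "fertilization_response",
    "community_weighted_mean",
    "summarize_communities",
    "compute_abundance_responses",
    "CWM_VARIABLES",
    "summaries_to_frame",
    "responses_to_frame",
]

#: The CWM variables entering the community-level analyses, keyed by the
#: display name used in result tables and mapped to the per-species trait
#: lookup name. Germination percentage at the five constant temperatures;
#: germination rate at 5, 10, 20 and 25 degC; niche breadth; occupation and
#: niche proportion at the five temperatures; and the two regime responses.
CWM_VARIABLES: dict[str, str] = {
    **{f"GP_{t}": f"GP_T{t}" for t in (5, 10, 15, 20, 25)},
    **{f"GR_{t}": f"GR_T{t}" for t in (5, 10, 20, 25)},
    "BTN": "BTN",
    **{f"O_{t}": f"O_{t}" for t in (5, 10, 15, 20, 25)},
    **{f"P_{t}": f"P_{t}" for t in (5, 10, 15, 20, 25)},
    "R_5_25": "R_5_25",
    "R_wc": "R_wc",
}


@dataclass
class SpeciesAbundanceResponse:
    """Per-species relative abundance by treatment and fertilization response."""

    species_id: str
    ra_by_level: dict[str, float]
    r_f: float | None

    @property
    def defined(self) -> bool:
        return self.r_f is not None


@dataclass
class CommunityTraitSummary:
    """Community-weighted means of all trait variables for one quadrat."""

    block_id: str
    n_level: NitrogenLevel
    cwm: dict[str, float | None] = field(default_factory=dict)
    coverage: dict[str, float | None] = field(default_factory=dict)


def relative_abundance(
    quadrats: Sequence[VegetationQuadrat], level: NitrogenLevel
) -> dict[str, float]:
    """Relative abundance RA_i = n_i / N at one treatment, pooled over blocks."""
    selected = [q for q in quadrats if q.n_level is level]
    if not selected:
        raise ValidationError(f"no quadrats at level {level.name}")
    totals: dict[str, int] = {}
    for q in selected:
        for sp, n in q.species_counts.items():
            totals[sp] = totals.get(sp, 0) + n
    grand = sum(totals.values())
    return {sp: n / grand for sp, n in sorted(totals.items())}


def fertilization_response(ra_n0: float, ra_n3: float) -> float | None:
    """R_f = (RA_N3 - RA_N0) / (RA_N3 + RA_N0); None when both are zero."""
    total = ra_n3 + ra_n0
    if total == 0:
        return None
    return (ra_n3 - ra_n0) / total


def compute_abundance_responses(
    quadrats: Sequence[VegetationQuadrat], pooling: str = "pooled"
) -> list[SpeciesAbundanceResponse]:
    """Per-species RA at every treatment plus the N3-vs-N0 response R_f.

    ``pooled`` (default) computes RA from counts summed over the replicate
    blocks of a treatment; ``per_block`` computes R_f within each block and
    averages over blocks where it is defined.
    """
    species = sorted({sp for q in quadrats for sp in q.species_counts})
    ra_by_level = {lv: relative_abundance(quadrats, lv) for lv in NitrogenLevel}

    responses = []
    for sp in species:
        ras = {lv.name: ra_by_level[lv].get(sp, 0.0) for lv in NitrogenLevel}
        if pooling == "pooled":
            r_f = fertilization_response(ras["N0"], ras["N3"])
        elif pooling == "per_block":
            vals = []
            blocks = sorted({q.block_id for q in quadrats})
            for b in blocks:
                sub = [q for q in quadrats if q.block_id == b]
                ra0 = relative_abundance(sub, NitrogenLevel.N0).get(sp, 0.0)
                ra3 = relative_abundance(sub, NitrogenLevel.N3).get(sp, 0.0)
                v = fertilization_response(ra0, ra3)
                if v is not None:
                    vals.append(v)
            r_f = float(np.mean(vals)) if vals else None
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        responses.append(SpeciesAbundanceResponse(species_id=sp, ra_by_level=ras, r_f=r_f))
    return responses


def community_weighted_mean(
    quadrat: VegetationQuadrat, trait_values: Mapping[str, float | None]
) -> tuple[float | None, float]:
    """CWM = Sum_i trait_i * RA_i over species with the trait defined.

    Weights are relative abundances renormalized over the included species,
    so the CWM is a convex combination of trait values. Coverage is the
    abundance share of included species before renormalization; a CWM over
    species carrying no abundance information (coverage 0) is undefined.
    """
    total = quadrat.total_individuals
    included = [
        (sp, n, trait_values[sp])
        for sp, n in quadrat.species_counts.items()
        if n > 0 and trait_values.get(sp) is not None
    ]
    covered = sum(n for _, n, _ in included)
    coverage = covered / total
    if covered == 0:
        return None, 0.0
    cwm = sum(n * v for _, n, v in included) / covered
    return float(cwm), float(coverage)


def summarize_communities(
    quadrats: Sequence[VegetationQuadrat],
    profiles: Iterable[SpeciesGermProfile],
    variables: Mapping[str, str] = CWM_VARIABLES,
) -> list[CommunityTraitSummary]:
    """One :class:`CommunityTraitSummary` per quadrat over all CWM variables."""
    prof_by_id = {p.species_id: p for p in profiles}
    summaries = []
    for q in sorted(quadrats, key=lambda q: (q.block_id, q.n_level.name)):
        summary = CommunityTraitSummary(block_id=q.block_id, n_level=q.n_level)
        for var, trait_name in variables.items():
            values = {
                sp: (prof_by_id[sp].trait_value(trait_name) if sp in prof_by_id else None)
                for sp in q.species_counts
            }
            cwm, coverage = community_weighted_mean(q, values)
            summary.cwm[var] = cwm
            summary.coverage[var] = coverage
        summaries.append(summary)
    return summaries


def summaries_to_frame(summaries: Sequence[CommunityTraitSummary]) -> pd.DataFrame:
    """Tidy quadrat x variable table of CWMs (one row per quadrat)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"block": s.block_id, "n_level": s.n_level.name}
        for var in CWM_VARIABLES:
            row[f"CWM_{var}"] = s.cwm.get(var)
        for var in CWM_VARIABLES:
            row[f"coverage_{var}"] = s.coverage.get(var)
        rows.append(row)
    return pd.DataFrame(rows)


def responses_to_frame(responses: Sequence[SpeciesAbundanceResponse]) -> pd.DataFrame:
    rows = []
    for r in responses:
        row: dict[str, object] = {"species_id": r.species_id}
        for lv in NitrogenLevel:
            row[f"RA_{lv.name}"] = r.ra_by_level.get(lv.name, 0.0)
        row["R_f"] = r.r_f
        rows.append(row)
    return pd.DataFrame(rows)
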