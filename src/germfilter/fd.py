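"""Functional-diversity indices over the germination-trait space.

Implements the three classical multidimensional indices of Villeger, Mason &
Mouillot (2008) for all-quantitative traits:

* FRic — functional richness: volume of the convex hull of a community's
  species in trait space;
* FEve — functional evenness: regularity of species packing and abundance
  along the community's minimum spanning tree, in [0, 1];
* FDiv — functional divergence: degree to which abundance is concentrated
  toward the extremes of the occupied trait space, in [0, 1].

The trait space is built once for all communities from seven variables
(germination percentage at the five constant temperatures and the responses
to alternating temperature and wet-cold storage), z-score standardized.
Communities are compared in one shared space with one shared dimensionality,
because richness volumes are only comparable on common axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .types import NitrogenLevel, ValidationError, VegetationQuadrat
from .traits import SpeciesGermProfile

__all__ = [
    "TraitSpace",
    "FDResult",
    "FD_TRAIT_VARIABLES",
    "build_trait_space",
    "fric",
    "feve",
    "fdiv",
    "fd_all",
    "fd_results_to_frame",
]

#: The seven quantitative variables spanning the germination-trait space.
FD_TRAIT_VARIABLES: tuple[str, ...] = (
    "GP_T5",
    "GP_T10",
    "GP_T15",
    "GP_T20",
    "GP_T25",
    "R_5_25",
    "R_wc",
)


@dataclass
class TraitSpace:
    """Shared standardized trait coordinates for all communities."""

    species_ids: list[str]
    coordinates: np.ndarray  # (n_species, m)
    axes_used: int
    dropped_species: list[tuple[str, str]] = field(default_factory=list)

    def index_of(self, species: Sequence[str]) -> np.ndarray:
        lookup = {sp: i for i, sp in enumerate(self.species_ids)}
        missing = [sp for sp in species if sp not in lookup]
        if missing:
            raise ValidationError(f"species not in trait space: {missing}")
        return np.array([lookup[sp] for sp in species], dtype=int)


@dataclass
class FDResult:
    block_id: str
    n_level: NitrogenLevel
    fric: float | None
    feve: float | None
    fdiv: float | None
    s_used: int


def _pcoa_coordinates(points: np.ndarray, m: int) -> np.ndarray:
    """First m principal coordinates of the Euclidean distance matrix.

    For Euclidean distances PCoA is exact (no negative eigenvalues beyond
    rounding), so hull volumes in the reduced space are the volumes of the
    orthogonally projected cloud.
    """
    d2 = squareform(pdist(points)) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :m] * np.sqrt(eigval[:m])
    return coords


def build_trait_space(
    profiles: Iterable[SpeciesGermProfile],
    m: int | str = "auto",
    quadrats: Sequence[VegetationQuadrat] | None = None,
) -> TraitSpace:
    """Standardized (optionally reduced) trait space over the 7 FD variables.

    Species missing any of the seven variables are dropped and recorded.
    With ``m="auto"`` the dimensionality adapts to the poorest community:
    m = min(7, S_min - 1) where S_min is the smallest per-community count of
    retained species (floor 2), because a hull in m dimensions needs more
    than m points. When m < 7 the coordinates are the first m principal
    coordinates of the Euclidean distance matrix on the standardized traits.
    """
    kept_ids, rows, dropped = [], [], []
    for p in profiles:
        values = [p.trait_value(v) for v in FD_TRAIT_VARIABLES]
        missing = [v for v, x in zip(FD_TRAIT_VARIABLES, values) if x is None]
        if missing:
            dropped.append((p.species_id, f"missing:{','.join(missing)}"))
        else:
            kept_ids.append(p.species_id)
            rows.append(values)
    if len(kept_ids) < 3:
        raise ValidationError(f"only {len(kept_ids)} species with all FD traits; need >= 3")

    x = np.asarray(rows, dtype=float)
    sd = x.std(axis=0, ddof=1)
    zero_var = [v for v, s in zip(FD_TRAIT_VARIABLES, sd) if s == 0]
    if zero_var:
        raise ValidationError(f"zero-variance trait column(s): {zero_var}")
    z = (x - x.mean(axis=0)) / sd

    n_traits = z.shape[1]
    if m == "auto":
        if quadrats:
            kept = set(kept_ids)
            s_min = min(
                sum(1 for sp, n in q.species_counts.items() if n > 0 and sp in kept)
                for q in quadrats
            )
        else:
            s_min = len(kept_ids)
        m_used = int(min(n_traits, max(2, s_min - 1)))
    else:
        m_used = int(m)
        if m_used < 1:
            raise ValidationError("m must be >= 1")
        m_used = min(m_used, n_traits)

    coords = z if m_used == n_traits else _pcoa_coordinates(z, m_used)
    return TraitSpace(
        species_ids=kept_ids,
        coordinates=coords,
        axes_used=m_used,
        dropped_species=dropped,
    )


def _community_points(
    space: TraitSpace, community: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    present = {sp for sp in space.species_ids} & {
        sp for sp, w in community.items() if w > 0
    }
    species = sorted(present)
    idx = space.index_of(species)
    pts = space.coordinates[idx]
    w = np.array([community[sp] for sp in species], dtype=float)
    return pts, w


def fric(space: TraitSpace, community: Mapping[str, float]) -> float | None:
    """Convex-hull volume of the community in trait space; None if degenerate.

    A hull in m dimensions needs at least m + 1 affinely independent points;
    communities below that (or exactly coplanar ones) have undefined FRic
    rather than a silently zero volume.
    """
    pts, _ = _community_points(space, community)
    m = space.axes_used
    if pts.shape[0] <= m:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    return float(hull.volume)


def feve(space: TraitSpace, community: Mapping[str, float]) -> float | None:
    """Minimum-spanning-tree evenness of species packing, weighted by abundance.

    Each MST branch l joining species i, j gets EW_l = dist(i,j)/(w_i + w_j);
    with PEW_l = EW_l / Sum EW and S species,
    FEve = (Sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).
    Equals 1 when branch lengths and abundances are perfectly regular.
    """
    pts, w = _community_points(space, community)
    s = pts.shape[0]
    if s < 3:
        return None
    w = w / w.sum()
    dist = squareform(pdist(pts))
    mst = minimum_spanning_tree(dist).tocoo()
    ew = np.array([dist[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    if ew.sum() == 0:  # all species at one point
        pew = np.full(s - 1, 1.0 / (s - 1))
    else:
        pew = ew / ew.sum()
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def fdiv(space: TraitSpace, community: Mapping[str, float]) -> float | None:
    """Abundance-weighted divergence from the hull-vertex centroid, in [0, 1].

    G is the centroid of the convex-hull vertices (unweighted); with dG_i the
    distance of species i to G, d-bar their unweighted mean, and w the
    normalized abundances, Delta d = Sum w_i (dG_i - d-bar) and
    Delta|d| = Sum w_i |dG_i - d-bar|:
    FDiv = (Delta d + d-bar) / (Delta |d| + d-bar).
    """
    pts, w = _community_points(space, community)
    m = space.axes_used
    if pts.shape[0] <= m:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    w = w / w.sum()
    g = pts[hull.vertices].mean(axis=0)
    dg = np.linalg.norm(pts - g, axis=1)
    dbar = dg.mean()
    delta_d = float(np.sum(w * (dg - dbar)))
    delta_abs = float(np.sum(w * np.abs(dg - dbar)))
    if delta_abs + dbar == 0:
        return 1.0
    return float((delta_d + dbar) / (delta_abs + dbar))


def fd_all(space: TraitSpace, quadrats: Sequence[VegetationQuadrat]) -> list[FDResult]:
    """All three indices per quadrat, with the number of species used."""
    results = []
    for q in sorted(quadrats, key=lambda q: (q.block_id, q.n_level.name)):
        community = {sp: float(n) for sp, n in q.species_counts.items() if n > 0}
        kept = {sp for sp in community if sp in set(space.species_ids)}
        community = {sp: community[sp] for sp in kept}
        results.append(
            FDResult(
                block_id=q.block_id,
                n_level=q.n_level,
                fric=fric(space, community),
                feve=feve(space, community),
                fdiv=fdiv(space, community),
                s_used=len(community),
            )
        )
    return results


def fd_results_to_frame(results: Sequence[FDResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "block": r.block_id,
                "n_level": r.n_level.name,
                "FRic": r.fric,
                "FEve": r.feve,
                "FDiv": r.fdiv,
                "s_used": r.s_used,
            }
            for r in results
        ]
    )
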