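"""Correlation-matrix PCA of community-weighted trait profiles.

Columns are standardized to zero mean and unit variance, so components are
eigenvectors of the correlation matrix; they are computed from the singular
value decomposition of the standardized data for numerical stability. Sign
convention: within each component the largest-magnitude loading is positive,
making results deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = ["PCAResult", "pca_cwm"]


@dataclass
class PCAResult:
    variable_names: tuple[str, ...]
    loadings: np.ndarray           # (n_variables, n_components), orthonormal columns
    scores: np.ndarray             # (n_observations, n_components)
    variance_explained: np.ndarray  # proportions, sums to 1

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        comps = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        loadings = pd.DataFrame(self.loadings, index=self.variable_names, columns=comps)
        scores = pd.DataFrame(self.scores, columns=comps)
        var = pd.DataFrame(
            {"component": comps, "variance_explained": self.variance_explained}
        )
        return loadings, scores, var


def pca_cwm(data: pd.DataFrame | np.ndarray, variable_names: Sequence[str] | None = None
            ) -> PCAResult:
    """PCA of a complete observations x variables matrix on the correlation
    scale.

    Rows with any missing cell must be removed by the caller (community
    summaries with undefined CWMs are dropped upstream, never imputed).
    Zero-variance columns are an error naming the column. All min(n, p)
    components are returned; their variance shares sum to 1.
    """
    if isinstance(data, pd.DataFrame):
        variable_names = tuple(map(str, data.columns))
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        variable_names = tuple(variable_names or (f"v{i + 1}" for i in range(x.shape[1])))
    n, p = x.shape
    if n < 3:
        raise ValidationError("PCA needs at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValidationError("PCA input contains missing or non-finite cells")

    sd = x.std(axis=0, ddof=1)
    dead = [variable_names[j] for j in range(p) if sd[j] == 0]
    if dead:
        raise ValidationError(f"zero-variance column(s): {dead}")
    z = (x - x.mean(axis=0)) / sd

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n, p)
    u, s, vt = u[:, :k], s[:k], vt[:k]

    # deterministic orientation: dominant loading of each component positive
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0

    eigvals = s**2 / (n - 1)
    return PCAResult(
        variable_names=variable_names,
        loadings=vt.T.copy(),
        scores=u * s,
        variance_explained=eigvals / eigvals.sum(),
    )
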