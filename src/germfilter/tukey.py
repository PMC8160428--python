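"""Tukey HSD between-group comparisons with compact letter display.

Group means are compared with the studentized-range criterion on the pooled
within-group (residual) variance; unbalanced designs use the Tukey-Kramer
standard error. Levels sharing a letter are not significantly different at
the configured family-wise level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

__all__ = ["TukeyResult", "tukey_groups", "compact_letter_display"]


@dataclass
class TukeyResult:
    levels: tuple[str, ...]
    means: dict[str, float]
    letters: dict[str, str]
    significant_pairs: list[tuple[str, str]]
    q_critical: float
    resid_var: float
    df_resid: float


def compact_letter_display(
    levels: Sequence[str], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment (Piepho 2004).

    Starts from one column containing every level; each significant pair
    splits any column containing both; columns that become subsets of others
    are absorbed. Letters are ordered by each column's first level.
    """
    columns: list[set[str]] = [set(levels)]
    for pair in significant:
        a, b = tuple(pair)
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = [
            c
            for i, c in enumerate(new_columns)
            if c and not any(c < other or (c == other and i > j)
                             for j, other in enumerate(new_columns))
        ]
    order = {lv: i for i, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(order[lv] for lv in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for i, col in enumerate(columns):
        for lv in levels:
            if lv in col:
                letters[lv] += alphabet[i]
    return letters


def tukey_groups(
    values: Mapping[str, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
    resid_var: float | None = None,
    df_resid: float | None = None,
    response: str | None = None,
    factor: str | None = None,
) -> TukeyResult:
    """Tukey HSD over the levels of one factor.

    ``values`` maps level -> observations (or is a tidy frame with
    ``response`` and ``factor`` columns). By default the residual variance is
    the pooled within-level variance (the one-way ANOVA mean square error);
    a model-based variance can be supplied with its degrees of freedom.
    """
    if isinstance(values, pd.DataFrame):
        if response is None or factor is None:
            raise ValidationError("response and factor column names required")
        grouped = {
            str(lv): sub[response].dropna().to_numpy(dtype=float)
            for lv, sub in values.groupby(factor, sort=False)
        }
    else:
        grouped = {str(lv): np.asarray(v, dtype=float) for lv, v in values.items()}

    levels = tuple(grouped)
    if len(levels) < 2:
        raise ValidationError("need at least two levels")
    ns = {lv: len(v) for lv, v in grouped.items()}
    if any(n < 2 for n in ns.values()):
        few = [lv for lv, n in ns.items() if n < 2]
        raise ValidationError(f"levels with fewer than 2 observations: {few}")
    means = {lv: float(np.mean(v)) for lv, v in grouped.items()}

    if resid_var is None:
        sse = sum(float(np.sum((v - means[lv]) ** 2)) for lv, v in grouped.items())
        df_resid = sum(ns.values()) - len(levels)
        resid_var = sse / df_resid if df_resid > 0 else 0.0
    elif df_resid is None:
        raise ValidationError("df_resid must accompany resid_var")

    k = len(levels)
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_resid))
    significant: set[frozenset[str]] = set()
    if resid_var > 0:
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                se = np.sqrt(resid_var / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                if abs(means[a] - means[b]) > q_crit * se:
                    significant.add(frozenset((a, b)))

    letters = compact_letter_display(levels, significant)
    return TukeyResult(
        levels=levels,
        means=means,
        letters=letters,
        significant_pairs=sorted(tuple(sorted(p)) for p in significant),
        q_critical=q_crit,
        resid_var=float(resid_var),
        df_resid=float(df_resid),
    )
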