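"""Gaussian linear mixed model with a single block random intercept.

Community-level responses (CWMs, FD indices) are modelled as
y = X beta + Z b + e with b ~ N(0, sigma_b^2 I) over blocks and
e ~ N(0, sigma_e^2 I). For a fixed variance ratio lambda = sigma_b^2 /
sigma_e^2 the GLS estimate of beta and the profiled log-likelihood are
closed-form (the marginal covariance is block-diagonal with V_k = I +
lambda J, invertible analytically), so the full ML fit reduces to a 1-D
search over log lambda. ML rather than REML is used throughout so that
likelihood-ratio chi-square tests between nested fixed-effect structures
are valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import ValidationError

__all__ = ["LMMFit", "LRTResult", "design_matrix", "fit_lmm", "lrt", "term_tests"]


@dataclass
class LMMFit:
    response: str
    fixed_terms: tuple[str, ...]
    coef_names: tuple[str, ...]
    beta: np.ndarray
    sigma_block2: float
    sigma_resid2: float
    loglik_ml: float
    n_obs: int

    @property
    def n_fixed(self) -> int:
        return len(self.coef_names)

    @property
    def fixed_effect_estimates(self) -> dict[str, float]:
        return dict(zip(self.coef_names, map(float, self.beta)))


@dataclass
class LRTResult:
    term: str
    chi2: float
    df: int
    p: float


def _dummies(series: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(series))
    cols = [(series == lv).to_numpy(dtype=float) for lv in levels[1:]]
    names = [f"{prefix}[{lv}]" for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(series), 0))), names


def design_matrix(
    df: pd.DataFrame, factors: Sequence[str], interactions: Sequence[tuple[str, str]] = ()
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effects design: intercept, main-effect dummies
    (first level as reference, in order of appearance) and products for any
    requested pairwise interactions."""
    n = len(df)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    main: dict[str, tuple[np.ndarray, list[str]]] = {}
    for f in factors:
        mat, cols = _dummies(df[f].astype(str), f)
        main[f] = (mat, cols)
        blocks.append(mat)
        names.extend(cols)
    for fa, fb in interactions:
        mat_a, cols_a = main[fa]
        mat_b, cols_b = main[fb]
        inter = []
        for i, ca in enumerate(cols_a):
            for j, cb in enumerate(cols_b):
                inter.append(mat_a[:, i] * mat_b[:, j])
                names.append(f"{ca}:{cb}")
        if inter:
            blocks.append(np.column_stack(inter))
    x = np.column_stack(blocks)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("singular fixed-effect design matrix")
    return x, names


def _block_solve(lam: float, block_sizes: np.ndarray, block_index: list[np.ndarray],
                 x: np.ndarray, y: np.ndarray):
    """GLS quantities for V = I + lam * ZZ' using the block-diagonal identity
    V_k^-1 = I - (lam / (1 + lam n_k)) J_k and |V_k| = 1 + lam n_k."""
    n, p = x.shape
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for nk, idx in zip(block_sizes, block_index):
        xk, yk = x[idx], y[idx]
        shrink = lam / (1.0 + lam * nk)
        xs = xk.sum(axis=0)
        ys = yk.sum()
        xtvx += xk.T @ xk - shrink * np.outer(xs, xs)
        xtvy += xk.T @ yk - shrink * xs * ys
        ytvy += yk @ yk - shrink * ys * ys
        logdet += math.log1p(lam * nk)
    beta = np.linalg.solve(xtvx, xtvy)
    # r'V^-1 r = y'V^-1 y - 2 b'X'V^-1 y + b'X'V^-1 X b
    rss = float(ytvy - 2.0 * beta @ xtvy + beta @ xtvx @ beta)
    return beta, rss, logdet, xtvx


def _profile_loglik(lam, block_sizes, block_index, x, y):
    n = len(y)
    _, rss, logdet, _ = _block_solve(lam, block_sizes, block_index, x, y)
    sigma_e2 = rss / n
    return -0.5 * (n * math.log(2.0 * math.pi * sigma_e2) + logdet + n)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
    block: str = "block",
) -> LMMFit:
    """ML fit of the random-intercept model by profiling the variance ratio.

    The profiled log-likelihood over log lambda is unimodal in well-behaved
    problems; it is maximized by bounded scalar search over
    log lambda in [-15, 15], with the boundary lambda = 0 (no block variance,
    i.e. ordinary least squares) checked explicitly.
    """
    df = data.dropna(subset=[response]).reset_index(drop=True)
    if df.empty:
        raise ValidationError(f"no observations for response {response!r}")
    y = df[response].to_numpy(dtype=float)
    x, names = design_matrix(df, factors, interactions)
    blocks = df[block].astype(str).to_numpy()
    labels = pd.unique(blocks)
    block_index = [np.flatnonzero(blocks == lb) for lb in labels]
    block_sizes = np.array([len(ix) for ix in block_index])
    n = len(y)

    neg = lambda log_lam: -_profile_loglik(math.exp(log_lam), block_sizes, block_index, x, y)
    res = optimize.minimize_scalar(neg, bounds=(-15.0, 15.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = math.exp(res.x)
    ll_interior = -res.fun
    ll_zero = _profile_loglik(0.0, block_sizes, block_index, x, y)
    if ll_zero >= ll_interior:
        lam, loglik = 0.0, ll_zero
    else:
        loglik = ll_interior

    beta, rss, _, _ = _block_solve(lam, block_sizes, block_index, x, y)
    sigma_e2 = rss / n
    all_terms = tuple(factors) + tuple(f"{a}:{b}" for a, b in interactions)
    return LMMFit(
        response=response,
        fixed_terms=all_terms,
        coef_names=tuple(names),
        beta=beta,
        sigma_block2=float(lam * sigma_e2),
        sigma_resid2=float(sigma_e2),
        loglik_ml=float(loglik),
        n_obs=n,
    )


def lrt(full: LMMFit, reduced: LMMFit) -> LRTResult:
    """Likelihood-ratio chi-square test of nested ML fits."""
    if full.n_obs != reduced.n_obs:
        raise ValidationError("LRT requires fits on the same observations")
    df = full.n_fixed - reduced.n_fixed
    if df < 0 or not set(reduced.coef_names) <= set(full.coef_names):
        raise ValidationError("reduced model is not nested in the full model")
    chi2 = max(0.0, 2.0 * (full.loglik_ml - reduced.loglik_ml))
    term = ",".join(sorted(set(full.fixed_terms) - set(reduced.fixed_terms))) or "(diff)"
    p = float(stats.chi2.sf(chi2, df)) if df > 0 and chi2 > 0 else 1.0
    return LRTResult(term=term, chi2=float(chi2), df=int(df), p=p)


def term_tests(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interaction: bool = False,
    block: str = "block",
) -> list[LRTResult]:
    """Per-term likelihood-ratio tests for the standard factorial analyses.

    With one factor: the factor is tested against the intercept-only model.
    With two factors and interaction: the interaction is tested against the
    additive model, and each main effect against the additive model with
    that term removed.
    """
    results = []
    if len(factors) == 1:
        full = fit_lmm(data, response, factors, block=block)
        null = fit_lmm(data, response, [], block=block)
        r = lrt(full, null)
        r.term = factors[0]
        results.append(r)
        return results

    fa, fb = factors
    additive = fit_lmm(data, response, [fa, fb], block=block)
    for term, reduced_factors in ((fa, [fb]), (fb, [fa])):
        reduced = fit_lmm(data, response, reduced_factors, block=block)
        r = lrt(additive, reduced)
        r.term = term
        results.append(r)
    if interaction:
        full = fit_lmm(data, response, [fa, fb], interactions=[(fa, fb)], block=block)
        r = lrt(full, additive)
        r.term = f"{fa}:{fb}"
        results.append(r)
    return results
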