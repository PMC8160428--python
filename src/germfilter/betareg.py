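"""Beta regression of the transformed fertilization response on germination
indices.

The response R_f lives in [-1, 1]; a beta-distributed response must lie
strictly inside (0, 1), so boundary cases (-1 and +1, i.e. species present in
only one of the contrasted treatments) are removed and the remainder mapped
with y -> (y + 1)/2. The model is the mean/precision parameterization of
Ferrari & Cribari-Neto (2004): y ~ Beta(mu * phi, (1 - mu) * phi) with
logit(mu) = b0 + b1 * x, fitted by maximum likelihood with analytic
gradients; standard errors come from the inverse observed information, and
the reported pseudo-R^2 is the squared Pearson correlation between logit(y)
and the fitted linear predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .traits import SpeciesGermProfile
from .community import SpeciesAbundanceResponse
from .types import TemperatureCondition, ValidationError

__all__ = [
    "BetaRegFit",
    "ConvergenceError",
    "prepare_beta_response",
    "beta_loglik",
    "beta_regression",
    "fit_all_species_regressions",
    "SPECIES_PREDICTORS",
    "fits_to_frame",
]

#: Predictors regressed against the transformed R_f, in report order:
#: GP and GR at the six incubation regimes, the two response contrasts,
#: niche breadth, and occupation/proportion at the five temperatures.
SPECIES_PREDICTORS: tuple[str, ...] = tuple(
    [f"GP_{c.name}" for c in TemperatureCondition]
    + [f"GR_{c.name}" for c in TemperatureCondition]
    + ["R_5_25", "R_wc", "BTN"]
    + [f"O_{t}" for t in (5, 10, 15, 20, 25)]
    + [f"P_{t}" for t in (5, 10, 15, 20, 25)]
)

MIN_CASES = 10


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the last iterate and gradient norm."""

    def __init__(self, message: str, last_params: np.ndarray, grad_norm: float):
        super().__init__(f"{message} (last iterate {last_params}, |grad| {grad_norm:.3g})")
        self.last_params = last_params
        self.grad_norm = grad_norm


@dataclass
class BetaRegFit:
    predictor_name: str
    intercept: float
    slope: float
    phi: float
    se_intercept: float
    se_slope: float
    z_slope: float
    p_slope: float
    pseudo_r2: float
    loglik: float
    n_used: int
    n_dropped_boundary: int
    n_dropped_undefined: int


def prepare_beta_response(
    r_values: Iterable[float | None], epsilon: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Boundary removal and (y + 1)/2 rescaling of response indices.

    Returns (transformed values, boolean keep-mask over the input order,
    n boundary-dropped, n undefined-dropped). Values within ``epsilon`` of
    -1 or +1 count as boundary cases.
    """
    raw = list(r_values)
    keep = np.zeros(len(raw), dtype=bool)
    out = []
    n_boundary = n_undefined = 0
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_undefined += 1
            continue
        v = float(v)
        if abs(abs(v) - 1.0) <= epsilon:
            n_boundary += 1
            continue
        if not -1.0 < v < 1.0:
            raise ValidationError(f"response value {v} outside [-1, 1]")
        keep[i] = True
        out.append((v + 1.0) / 2.0)
    return np.asarray(out, dtype=float), keep, n_boundary, n_undefined


def beta_loglik(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood at params = (b0, b1, log phi)."""
    b0, b1, log_phi = params
    phi = math.exp(log_phi)
    mu = special.expit(b0 + b1 * x)
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def _neg_loglik_grad(params: np.ndarray, x: np.ndarray, y: np.ndarray):
    b0, b1, log_phi = params
    phi = math.exp(log_phi)
    eta = b0 + b1 * x
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    log_y = np.log(y)
    log_1my = np.log1p(-y)

    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * log_y
        + (b - 1.0) * log_1my
    )
    y_star = log_y - log_1my
    mu_star = special.digamma(a) - special.digamma(b)
    w = phi * (y_star - mu_star) * mu * (1.0 - mu)
    d_b0 = np.sum(w)
    d_b1 = np.sum(w * x)
    d_phi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * log_y
        + (1.0 - mu) * log_1my
    )
    grad = np.array([d_b0, d_b1, d_phi * phi])  # chain rule for log-phi scale
    return -float(ll), -grad


def _hessian_fd(params: np.ndarray, x: np.ndarray, y: np.ndarray, h: float = 1e-5):
    """Observed information (negative-loglik Hessian) by central differences
    of the analytic gradient."""
    k = params.size
    hess = np.zeros((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = h * max(1.0, abs(params[j]))
        _, g_plus = _neg_loglik_grad(params + step, x, y)
        _, g_minus = _neg_loglik_grad(params - step, x, y)
        hess[:, j] = (g_plus - g_minus) / (2.0 * step[j])
    return (hess + hess.T) / 2.0


def beta_regression(
    y: Sequence[float], x: Sequence[float], predictor_name: str = "x", max_iter: int = 500
) -> BetaRegFit:
    """Fit the two-parameter-mean, constant-precision beta regression by ML."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValidationError("y and x must have equal length")
    if y.size < MIN_CASES:
        raise ValidationError(
            f"{predictor_name}: only {y.size} cases after boundary removal; "
            f"need >= {MIN_CASES}"
        )
    if np.any((y <= 0) | (y >= 1)):
        raise ValidationError("responses must lie strictly inside (0, 1)")
    if not np.all(np.isfinite(x)) or x.std() == 0:
        raise ValidationError(f"{predictor_name}: predictor must be finite with nonzero variance")

    # Start values: OLS of logit(y) on x; phi from the mean-variance relation.
    logit_y = special.logit(y)
    slope0, intercept0 = np.polyfit(x, logit_y, 1)
    mu0 = special.expit(intercept0 + slope0 * x)
    resid_var = max(np.var(y - mu0, ddof=2), 1e-6)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0), 1.0)
    start = np.array([intercept0, slope0, math.log(phi0)])

    res = optimize.minimize(
        _neg_loglik_grad,
        start,
        args=(x, y),
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    # Newton polish with backtracking: BFGS can stop on precision loss with a
    # small but nonzero gradient; a few damped Newton steps push it to ~0.
    theta = res.x
    nll, grad = _neg_loglik_grad(theta, x, y)
    for _ in range(50):
        if np.linalg.norm(grad) < 1e-8:
            break
        hess = _hessian_fd(theta, x, y)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = theta - scale * step
            nll_cand, grad_cand = _neg_loglik_grad(cand, x, y)
            if np.isfinite(nll_cand) and nll_cand <= nll:
                theta, nll, grad = cand, nll_cand, grad_cand
                break
            scale *= 0.5
        else:
            break
    grad_norm = float(np.linalg.norm(grad))
    if grad_norm > 1e-4 * max(1.0, math.sqrt(y.size)):
        raise ConvergenceError(
            f"{predictor_name}: beta regression did not converge in {max_iter} iterations",
            theta,
            grad_norm,
        )
    res_x, res_fun = theta, nll

    b0, b1, log_phi = res_x
    info = _hessian_fd(res_x, x, y)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            f"{predictor_name}: singular observed information", res_x, grad_norm
        ) from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = b1 / se[1] if se[1] > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(z))
    eta = b0 + b1 * x
    pseudo_r2 = float(np.corrcoef(logit_y, eta)[0, 1] ** 2)

    return BetaRegFit(
        predictor_name=predictor_name,
        intercept=float(b0),
        slope=float(b1),
        phi=float(math.exp(log_phi)),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        z_slope=float(z),
        p_slope=float(p),
        pseudo_r2=pseudo_r2,
        loglik=-float(res_fun),
        n_used=int(y.size),
        n_dropped_boundary=0,
        n_dropped_undefined=0,
    )


def fit_all_species_regressions(
    responses: Sequence[SpeciesAbundanceResponse],
    profiles: Sequence[SpeciesGermProfile],
    epsilon: float = 1e-9,
    predictors: Sequence[str] = SPECIES_PREDICTORS,
) -> tuple[list[BetaRegFit], dict[str, str]]:
    """One beta regression per germination index against transformed R_f.

    Species with an undefined response or predictor, or a boundary response,
    are dropped per fit. Fits that cannot run (too few cases, constant
    predictor) are skipped and reported in the returned error map.
    """
    prof_by_id = {p.species_id: p for p in profiles}
    fits: list[BetaRegFit] = []
    errors: dict[str, str] = {}
    for name in predictors:
        pairs = []
        n_undef = 0
        for r in responses:
            prof = prof_by_id.get(r.species_id)
            value = prof.trait_value(name) if prof is not None else None
            if value is None or r.r_f is None:
                n_undef += 1
                continue
            pairs.append((r.r_f, float(value)))
        raw_y = [p[0] for p in pairs]
        y, keep, n_boundary, _ = prepare_beta_response(raw_y, epsilon)
        x = np.asarray([p[1] for p in pairs], dtype=float)[keep]
        try:
            fit = beta_regression(y, x, predictor_name=name)
        except (ValidationError, ConvergenceError) as exc:
            errors[name] = str(exc)
            continue
        fit.n_dropped_boundary = n_boundary
        fit.n_dropped_undefined = n_undef
        fits.append(fit)
    return fits, errors


def fits_to_frame(fits: Sequence[BetaRegFit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "predictor": f.predictor_name,
                "intercept": f.intercept,
                "slope": f.slope,
                "phi": f.phi,
                "se_intercept": f.se_intercept,
                "se_slope": f.se_slope,
                "z": f.z_slope,
                "p": f.p_slope,
                "pseudo_r2": f.pseudo_r2,
                "loglik": f.loglik,
                "n_used": f.n_used,
                "n_dropped_boundary": f.n_dropped_boundary,
                "n_dropped_undefined": f.n_dropped_undefined,
            }
            for f in fits
        ]
    )
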