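"""Natural-effects causal mediation.

Continuous outcomes use the product-of-coefficients decomposition of the
linear structural model (nie = a*b, nde = c', te = c' + a*b) with a
row-resampling percentile bootstrap for inference. Binary outcomes use an
imputation-based natural-effects model on the log-odds scale: each row is
duplicated with a counterfactual exposure for the direct path, the
expected outcome is imputed from the observed-data logistic fit, and the
natural-effects logistic model is fit to the expanded data. A
mediator-outcome confounding sensitivity analysis reports the residual
correlation at which the indirect effect would vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .simulate import _logistic_newton


@dataclass
class MediationResult:
    nde: float
    nie: float
    te: float
    prop_mediated: float | None
    p_direct: float
    p_indirect: float
    p_total: float
    ci_nde: tuple
    ci_nie: tuple
    ci_te: tuple
    n_boot: int
    scale: str
    discordant: bool
    # internals needed by the sensitivity analysis
    a: float = np.nan
    b: float = np.nan
    sigma_mediator: float = np.nan
    sigma_outcome: float = np.nan


@dataclass
class SensitivityResult:
    rho_grid: np.ndarray
    nie_at_rho: np.ndarray
    rho_star: float | None  # None: no sign change inside the grid


def _design(x, covariates):
    x = np.asarray(x, dtype=float)
    cols = [np.ones(len(x)), x]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    return np.column_stack(cols)


def _boot_p(draws, point):
    """Two-sided bootstrap p by inversion: 2*min(P(draw<=0), P(draw>=0))."""
    draws = np.asarray(draws)
    lo = np.mean(draws <= 0.0)
    hi = np.mean(draws >= 0.0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _ci(draws):
    return (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))


def _discordant(nde, nie):
    """Strict sign conflict; effects at numerical zero count as concordant."""
    tol = 1e-10 * (abs(nde) + abs(nie))
    return (nde * nie < 0) and abs(nde) > tol and abs(nie) > tol


def _linear_paths(exposure, mediator, outcome, covariates):
    """(a, c', b, mediator residual SD, outcome residual SD)."""
    Xm = _design(exposure, covariates)
    cm, *_ = np.linalg.lstsq(Xm, mediator, rcond=None)
    a = cm[1]
    res_m = mediator - Xm @ cm
    Xy = np.column_stack([Xm[:, :2], mediator,
                          Xm[:, 2:]]) if Xm.shape[1] > 2 else \
        np.column_stack([Xm, mediator])
    cy, *_ = np.linalg.lstsq(Xy, outcome, rcond=None)
    c_prime, b = cy[1], cy[2]
    res_y = outcome - Xy @ cy
    return a, c_prime, b, res_m.std(ddof=Xm.shape[1]), res_y.std(ddof=Xy.shape[1])


def mediate_continuous(exposure, mediator, outcome, covariates=None,
                       n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Linear natural-effects decomposition with percentile bootstrap.

    Point estimates are the deterministic product-of-coefficients values;
    only the CIs and p-values are resampled.
    """
    if n_boot < 100:
        raise InsufficientDataError("n_boot must be >= 100 for stable intervals")
    exposure = np.asarray(exposure, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = len(exposure)
    ncov = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).shape[1]
    if n <= ncov + 3:
        raise InsufficientDataError("too few rows for the mediation fits")

    a, c_prime, b, sd_m, sd_y = _linear_paths(exposure, mediator, outcome, covariates)
    nie, nde = a * b, c_prime
    te = nde + nie

    rng = np.random.default_rng(seed)
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    draws = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Cb = None if C is None else C[idx]
        ab, cb, bb, *_ = _linear_paths(exposure[idx], mediator[idx], outcome[idx], Cb)
        draws[i] = (cb, ab * bb, cb + ab * bb)

    discordant = _discordant(nde, nie)
    prop = None if discordant or te == 0 else float(nie / te)
    return MediationResult(
        nde=float(nde), nie=float(nie), te=float(te), prop_mediated=prop,
        p_direct=_boot_p(draws[:, 0], nde),
        p_indirect=_boot_p(draws[:, 1], nie),
        p_total=_boot_p(draws[:, 2], te),
        ci_nde=_ci(draws[:, 0]), ci_nie=_ci(draws[:, 1]), ci_te=_ci(draws[:, 2]),
        n_boot=n_boot, scale="linear", discordant=bool(discordant),
        a=float(a), b=float(b), sigma_mediator=float(sd_m), sigma_outcome=float(sd_y))


def _natural_effects_binary(exposure, mediator, outcome, covariates, rng):
    """One pass of the imputation-based natural-effects estimator.

    Returns (nde, nie) on the log-odds scale.
    """
    from scipy.special import expit

    n = len(exposure)
    Xobs = _design(exposure, covariates)
    Xobs = np.column_stack([Xobs[:, :2], mediator, Xobs[:, 2:]])
    beta_obs, cov = _logistic_newton(Xobs, outcome, np.zeros(Xobs.shape[1]))
    if cov is None:
        raise np.linalg.LinAlgError("singular observed-data logistic fit")

    # expand: each row duplicated with a counterfactual direct-path
    # exposure x* drawn (by permutation) from the observed distribution
    x_star = exposure[rng.permutation(n)]
    x_dir = np.concatenate([exposure, x_star])      # direct-path exposure
    x_ind = np.concatenate([exposure, exposure])    # mediator-path exposure
    med = np.concatenate([mediator, mediator])      # mediator at observed x
    C2 = None if covariates is None else np.vstack([covariates, covariates])

    Ximp = _design(x_dir, C2)
    Ximp = np.column_stack([Ximp[:, :2], med, Ximp[:, 2:]])
    y_imp = expit(Ximp @ beta_obs)

    Xne = _design(x_dir, C2)
    Xne = np.column_stack([Xne[:, :2], x_ind, Xne[:, 2:]])
    beta_ne, cov_ne = _logistic_newton(Xne, y_imp, np.zeros(Xne.shape[1]))
    if cov_ne is None:
        raise np.linalg.LinAlgError("singular natural-effects fit")
    return float(beta_ne[1]), float(beta_ne[2])


def mediate_binary(exposure, mediator, outcome, covariates=None,
                   n_boot: int = 500, seed: int = 0,
                   min_events: int = 20) -> MediationResult:
    """Imputation-based natural-effects mediation for a binary outcome.

    Effects are on the log-odds scale; proportion mediated is
    nie / (nde + nie). The whole imputation procedure is bootstrapped.
    """
    if n_boot < 100:
        raise InsufficientDataError("n_boot must be >= 100 for stable intervals")
    exposure = np.asarray(exposure, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if outcome.sum() < min_events:
        raise InsufficientDataError(
            f"only {int(outcome.sum())} events; need >= {min_events}")
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    rng = np.random.default_rng(seed)
    nde, nie = _natural_effects_binary(exposure, mediator, outcome, C, rng)
    te = nde + nie

    n = len(exposure)
    draws = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Cb = None if C is None else C[idx]
        try:
            d, ind = _natural_effects_binary(exposure[idx], mediator[idx],
                                             outcome[idx], Cb, rng)
        except Exception:
            d, ind = np.nan, np.nan
        draws[i] = (d, ind, d + ind)
    draws = draws[np.isfinite(draws).all(axis=1)]

    discordant = _discordant(nde, nie)
    prop = None if discordant or te == 0 else float(nie / te)
    return MediationResult(
        nde=nde, nie=nie, te=float(te), prop_mediated=prop,
        p_direct=_boot_p(draws[:, 0], nde),
        p_indirect=_boot_p(draws[:, 1], nie),
        p_total=_boot_p(draws[:, 2], te),
        ci_nde=_ci(draws[:, 0]), ci_nie=_ci(draws[:, 1]), ci_te=_ci(draws[:, 2]),
        n_boot=int(len(draws)), scale="log_odds", discordant=bool(discordant))


def classify_mediation(result: MediationResult, threshold: float = 0.05) -> str:
    """{full, partial, none, discordant} per the significance pattern.

    full: indirect and total significant, direct not; partial: all three
    significant with concordant signs; discordant: direct and indirect
    significant with opposite signs.
    """
    sig_d = result.p_direct < threshold
    sig_i = result.p_indirect < threshold
    sig_t = result.p_total < threshold
    if result.nde * result.nie < 0 and sig_d and sig_i:
        return "discordant"
    if sig_i and sig_t and not sig_d:
        return "full"
    if sig_i and sig_t and sig_d and result.nde * result.nie >= 0:
        return "partial"
    return "none"


def sensitivity_rho(result: MediationResult, rho_grid=None) -> SensitivityResult:
    """Mediator-outcome confounding sensitivity for the linear model.

    nie(rho) = a * (b - rho * sigma_outcome_resid / sigma_mediator_resid);
    rho_star is the smallest |rho| on the grid at which the indirect
    effect crosses zero (None when no crossing lies inside the grid).
    """
    if result.scale != "linear":
        raise ValueError("sensitivity analysis applies to the linear scale only")
    if rho_grid is None:
        rho_grid = np.arange(-0.9, 0.91, 0.05)
    rho_grid = np.asarray(rho_grid, dtype=float)
    ratio = result.sigma_outcome / result.sigma_mediator
    nie = result.a * (result.b - rho_grid * ratio)
    if result.b == 0 or result.a == 0:
        rho_star = 0.0
    else:
        root = result.b / ratio
        rho_star = float(root) if rho_grid.min() <= root <= rho_grid.max() else None
    return SensitivityResult(rho_grid=rho_grid, nie_at_rho=nie, rho_star=rho_star)
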