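"""Associations of the risk score with secondary COPD phenotypes.

Continuous CT imaging measures (optionally log-transformed) use ordinary
linear regression.  Local-histogram emphysema percentages are zero-censored
by construction, so they use Tobit regression: a Gaussian linear model for a
latent variable observed only when positive, fitted by maximum likelihood,
with effects reported on the latent uncensored scale.  Visual emphysema
grade uses a proportional-odds ordinal logistic model.  CT subtypes are each
compared with the normal-imaging reference by logistic regression with
Bonferroni-widened CIs.  GOLD/PRISm category contrasts use Welch's
two-sample test, and lung-growth patterns (reduced vs normal growth) use
logistic regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.numdiff import approx_hess

from .evaluate import AssociationResult, SeparationError, _logistic, _score_array

logger = logging.getLogger(__name__)

__all__ = [
    "TobitResult",
    "OrdinalResult",
    "continuous_assoc",
    "tobit_assoc",
    "ordinal_assoc",
    "subtype_vs_reference",
    "gold_contrasts",
    "growth_pattern_assoc",
]

#: Bonferroni family threshold for the 20 imaging phenotypes
IMAGING_FAMILY_ALPHA = 0.0025


@dataclass
class TobitResult:
    """Left-censored Gaussian regression result on the latent scale."""

    beta_latent: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    sigma: float
    sigma_se: float
    n: int
    n_censored: int
    params: np.ndarray = field(default=None, repr=False)
    grad_norm: float = np.nan
    loglik: float = np.nan


@dataclass
class OrdinalResult:
    or_per_sd: float
    se: float           # on the log-odds scale
    ci_low: float       # OR scale
    ci_high: float
    p: float
    thresholds: np.ndarray
    n: int

    @property
    def log_or(self) -> float:
        return float(np.log(self.or_per_sd))


def _design(ph: pd.DataFrame, score, covariates: Sequence[str]):
    s = _score_array(score)
    cov = ph[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(s), 0))
    return s, cov


def continuous_assoc(
    ph: pd.DataFrame,
    score,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex", "pack_years"),
    transform: str = "none",
    log_offset: float | None = None,
    with_fev1_adjustment: bool = False,
    level: float = 0.95,
):
    """Linear regression of a (possibly log-transformed) outcome on the score.

    ``transform='log'`` requires positive values; zeros are handled by adding
    ``log_offset`` (default: half the smallest positive observed value),
    flagged in the result.  With ``with_fev1_adjustment`` a second fit that
    additionally adjusts for FEV1 %pred is returned side by side.
    """
    y = ph[outcome].to_numpy(dtype=float)
    flags = []
    if transform == "log":
        if (y < 0).any():
            raise ValueError(f"{outcome}: negative values cannot be log-transformed")
        if (y == 0).any():
            if log_offset is None:
                pos = y[y > 0]
                if len(pos) == 0:
                    raise ValueError(f"{outcome}: no positive values under log transform")
                log_offset = pos.min() / 2
            flags.append(f"log offset {log_offset:g} applied to zero values")
            y = np.log(y + log_offset)
        else:
            y = np.log(y)
    elif transform != "none":
        raise ValueError("transform must be 'none' or 'log'")

    def _fit(cov_names):
        s, cov = _design(ph, score, cov_names)
        X = sm.add_constant(np.column_stack([s, cov]), has_constant="add")
        fit = sm.OLS(y, X).fit()
        est, se = float(fit.params[1]), float(fit.bse[1])
        z = stats.norm.isf((1 - level) / 2)
        return AssociationResult(
            estimate=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
            p=float(fit.pvalues[1]), n=int(fit.nobs),
            model=f"{transform}({outcome}) ~ score + {'+'.join(cov_names) or '1'}",
            flags=list(flags),
        )

    base = _fit(list(covariates))
    if with_fev1_adjustment:
        return base, _fit(list(covariates) + ["fev1_pct_pred"])
    return base


def _tobit_loglik_grad(theta, X, y, censored):
    """Negative log-likelihood and gradient for left-censoring at 0."""
    beta, eta = theta[:-1], theta[-1]
    sigma = np.exp(eta)
    xb = X @ beta
    ll = 0.0
    grad_beta = np.zeros_like(beta)
    grad_eta = 0.0

    unc = ~censored
    if unc.any():
        z = (y[unc] - xb[unc]) / sigma
        ll += -0.5 * (z**2).sum() - unc.sum() * (eta + 0.5 * np.log(2 * np.pi))
        grad_beta += X[unc].T @ z / sigma
        grad_eta += (z**2 - 1.0).sum()
    if censored.any():
        c = -xb[censored] / sigma
        log_cdf = stats.norm.logcdf(c)
        ll += log_cdf.sum()
        lam = np.exp(stats.norm.logpdf(c) - log_cdf)  # inverse Mills ratio
        grad_beta += -(X[censored].T @ lam) / sigma
        grad_eta += (lam * (-c)).sum()
    grad = np.concatenate([grad_beta, [grad_eta]])
    return -ll, -grad


def tobit_assoc(
    ph: pd.DataFrame,
    score,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex", "pack_years"),
    censor_point: float = 0.0,
    level: float = 0.95,
) -> TobitResult:
    """Tobit (left-censored Gaussian) regression of a zero-censored outcome.

    Observations at or below ``censor_point`` are treated as censored.
    Maximum likelihood on (beta, log sigma), initialized from OLS on the
    uncensored subset; standard errors from the inverse observed information.
    The per-SD slope is reported on the latent uncensored scale.
    """
    y_raw = ph[outcome].to_numpy(dtype=float) - censor_point
    censored = y_raw <= 0
    n = len(y_raw)
    if censored.all():
        raise ValueError(f"{outcome}: fully censored, Tobit model undefined")
    s, cov = _design(ph, score, covariates)
    X = sm.add_constant(np.column_stack([s, cov]), has_constant="add")

    ols = sm.OLS(y_raw[~censored], X[~censored]).fit()
    resid_sd = float(np.sqrt(ols.scale)) if ols.df_resid > 0 else 1.0
    theta0 = np.concatenate([ols.params, [np.log(max(resid_sd, 1e-3))]])

    res = optimize.minimize(
        _tobit_loglik_grad, theta0, args=(X, y_raw, censored),
        jac=True, method="BFGS", options={"maxiter": 500, "gtol": 1e-8},
    )
    nll, grad = _tobit_loglik_grad(res.x, X, y_raw, censored)
    grad_norm = float(np.linalg.norm(grad))
    if not np.isfinite(nll) or grad_norm > 1e-3 * max(1.0, n):
        raise RuntimeError(
            f"Tobit fit did not converge (||grad||={grad_norm:.3g}, message={res.message!r})"
        )
    H = approx_hess(res.x, lambda t: _tobit_loglik_grad(t, X, y_raw, censored)[0])
    cov_theta = np.linalg.inv(H)
    est = float(res.x[1])
    se = float(np.sqrt(cov_theta[1, 1]))
    sigma = float(np.exp(res.x[-1]))
    sigma_se = float(sigma * np.sqrt(cov_theta[-1, -1]))  # delta method from log sigma
    z = stats.norm.isf((1 - level) / 2)
    return TobitResult(
        beta_latent=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
        p=float(2 * stats.norm.sf(abs(est / se))), sigma=sigma, sigma_se=sigma_se,
        n=n, n_censored=int(censored.sum()), params=res.x,
        grad_norm=grad_norm, loglik=float(-nll),
    )


def ordinal_assoc(
    ph: pd.DataFrame,
    score,
    ordered_outcome: str,
    covariates: Sequence[str] = ("age", "sex", "pack_years"),
    level: float = 0.95,
) -> OrdinalResult:
    """Proportional-odds model: OR per SD of being in a higher category."""
    y = ph[ordered_outcome]
    levels = np.sort(y.unique())
    if len(levels) < 2:
        raise ValueError("ordinal outcome needs at least 2 categories")
    counts = y.value_counts()
    if (counts < 1).any() or len(counts) != len(levels):
        raise ValueError("every ordinal category must be non-empty")
    s, cov = _design(ph, score, covariates)
    X = np.column_stack([s, cov])
    y_cat = pd.Categorical(y, categories=levels, ordered=True)
    model = OrderedModel(np.asarray(y_cat.codes), X, distr="logit")
    fit = model.fit(method="bfgs", disp=0, maxiter=1000, gtol=1e-08)
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    if not np.all(np.isfinite(params)) or abs(params[0]) > 50:
        raise SeparationError("separation detected in ordinal model")
    est, se = float(params[0]), float(bse[0])
    z = stats.norm.isf((1 - level) / 2)
    thr = model.transform_threshold_params(params)[1:-1]  # drop -inf/+inf
    return OrdinalResult(
        or_per_sd=float(np.exp(est)), se=se,
        ci_low=float(np.exp(est - z * se)), ci_high=float(np.exp(est + z * se)),
        p=float(fit.pvalues[0]), thresholds=np.asarray(thr), n=len(y),
    )


def subtype_vs_reference(
    ph: pd.DataFrame,
    score,
    subtype_column: str = "ct_subtype",
    reference=1,
    covariates: Sequence[str] = ("age", "sex", "pack_years"),
    n_comparisons: int | None = None,
) -> dict:
    """Logistic OR of each CT subtype vs the normal-imaging reference.

    Each non-reference subtype is compared to the reference in the subset of
    individuals holding either label.  CIs are Bonferroni-widened to level
    1 - 0.05/n_comparisons.  Subtypes with fewer than 2 individuals are
    skipped (logged).
    """
    lab = ph[subtype_column]
    ref_mask = lab == reference
    if ref_mask.sum() == 0:
        raise ValueError(f"reference category {reference!r} is empty")
    others = [v for v in np.sort(lab.dropna().unique()) if v != reference]
    if n_comparisons is None:
        n_comparisons = len(others)
    level = 1 - 0.05 / max(n_comparisons, 1)
    s = _score_array(score)
    out = {}
    for v in others:
        m = (lab == v) | ref_mask
        if (lab == v).sum() < 2:
            logger.warning("subtype %r has < 2 individuals, skipped", v)
            continue
        sub = ph.loc[m]
        y = (lab[m] == v).to_numpy(dtype=float)
        cov = sub[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((m.sum(), 0))
        X = np.column_stack([s[m.to_numpy()], cov])
        fit = _logistic(y, X, ["score"] + list(covariates))
        est, se = float(fit.params[1]), float(fit.bse[1])
        z = stats.norm.isf((1 - level) / 2)
        out[v] = AssociationResult(
            estimate=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
            p=float(fit.pvalues[1]), n=int(m.sum()),
            model=f"subtype {v} vs {reference} (CI level {level:.4f})",
        )
    return out


def gold_contrasts(
    ph: pd.DataFrame,
    score,
    pairs: Sequence[tuple[str, str]] = (("PRISm", "GOLD0"), ("PRISm", "GOLD1")),
) -> dict:
    """Welch two-sample comparisons of mean score between GOLD categories."""
    s = _score_array(score)
    cats = ph["gold_category"]
    out = {}
    for a, b in pairs:
        xa = s[(cats == a).to_numpy()]
        xb = s[(cats == b).to_numpy()]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("contrast %s vs %s skipped: category too small", a, b)
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        diff = float(xa.mean() - xb.mean())
        se = float(np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb)))
        z = stats.norm.isf(0.025)
        out[(a, b)] = AssociationResult(
            estimate=diff, se=se, ci_low=diff - z * se, ci_high=diff + z * se,
            p=float(p), n=len(xa) + len(xb), model=f"mean score: {a} vs {b} (Welch)",
        )
    return out


def growth_pattern_assoc(
    ph: pd.DataFrame,
    score,
    covariates: Sequence[str] = (
        "age", "sex", "height", "fev1_l", "bronchodilator_response", "airway_hyperresponsiveness",
    ),
    level: float = 0.95,
) -> AssociationResult:
    """Reduced vs normal lung-growth pattern, logistic on the score.

    Pools reduced-normal + reduced-early against normal-normal +
    normal-early, mirroring the growth/decline cross-classification.
    """
    missing = [c for c in covariates if c not in ph.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    pattern = ph["growth_pattern"].astype(str)
    y = pattern.str.startswith("reduced").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both growth classes must be non-empty")
    s, cov = _design(ph, score, covariates)
    X = np.column_stack([s, cov])
    fit = _logistic(y, X, ["score"] + list(covariates))
    est, se = float(fit.params[1]), float(fit.bse[1])
    z = stats.norm.isf((1 - level) / 2)
    return AssociationResult(
        estimate=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
        p=float(fit.pvalues[1]), n=len(y),
        model="reduced vs normal lung growth ~ score + covariates",
    )
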