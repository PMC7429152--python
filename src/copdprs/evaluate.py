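"""Per-cohort epidemiological evaluation of a polygenic risk score.

Covers the within-cohort analyses run against COPD status: the covariate-
adjusted odds ratio per standard deviation of the score, decile/tertile risk
stratification, AUC-based model comparison (score alone, clinical risk
factors alone, both together), Youden-index screening cutoffs, an externally
derived clinical risk score baseline, and exacerbation models with and
without adjustment for baseline lung function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .engine import PRSProfile
from .roc import delong_test, delong_variance, mann_whitney_auc, roc_curve_points

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "RocResult",
    "ScreeningMetrics",
    "SeparationError",
    "fit_or_per_sd",
    "assign_deciles",
    "decile_analysis",
    "auc_models",
    "youden_and_metrics",
    "clinical_risk_score",
    "exacerbation_models",
]

#: Bonferroni threshold reported when comparing models across 10 subpopulations
AUC_FAMILY_ALPHA = 0.005


class SeparationError(RuntimeError):
    """Logistic fit produced a non-finite estimate (perfect separation)."""


@dataclass
class AssociationResult:
    """An effect estimate with uncertainty.

    ``estimate`` is on the model's natural scale: log-odds for logistic
    models (use :attr:`odds_ratio`), the slope for linear models.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model: str = ""
    flags: list = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    curve: list  # (sensitivity, specificity, threshold)
    model: str = ""
    #: pairwise DeLong comparisons vs earlier models: (other, delta_auc, p)
    comparisons: list = field(default_factory=list)

    @property
    def comparison(self) -> tuple | None:
        """Comparison against the immediately preceding model, if any."""
        return self.comparisons[-1] if self.comparisons else None


@dataclass
class ScreeningMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    flags: list = field(default_factory=list)


def _score_array(score) -> np.ndarray:
    if isinstance(score, PRSProfile):
        return score.std
    return np.asarray(score, dtype=float)


def _logistic(y, X, names, level=0.95):
    """Fit a logistic model; raise SeparationError on non-finite estimates."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    bad = ~(np.isfinite(params) & np.isfinite(bse) & (np.abs(params) < 50))
    if bad.any():
        term = (["const"] + list(names))[int(np.nonzero(bad)[0][0])]
        raise SeparationError(f"separation detected for term {term!r}")
    return fit


def fit_or_per_sd(
    ph: pd.DataFrame,
    score,
    covariates: Sequence[str] = ("age", "sex", "height", "pack_years"),
    outcome: str = "copd",
    level: float = 0.95,
) -> AssociationResult:
    """Logistic regression of COPD on the standardized score plus covariates.

    Returns the per-SD log-odds ratio with Wald CI and two-sided p.
    """
    s = _score_array(score)
    y = ph[outcome].to_numpy(dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(s)
    cov = ph.loc[mask, list(covariates)].to_numpy(dtype=float) if covariates else np.empty((mask.sum(), 0))
    y = y[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([s[mask], cov])
    fit = _logistic(y, X, ["score"] + list(covariates))
    z = stats.norm.isf((1 - level) / 2)
    est, se = float(fit.params[1]), float(fit.bse[1])
    return AssociationResult(
        estimate=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
        p=float(fit.pvalues[1]), n=int(mask.sum()),
        model=f"{outcome} ~ score + {'+'.join(covariates) if covariates else '1'}",
    )


def assign_deciles(scores, n_groups: int = 10) -> np.ndarray:
    """Rank-based decile membership (1..n_groups); ties fall in the lower bin."""
    s = np.asarray(scores, dtype=float)
    if np.all(s == s[0]):
        raise ValueError("degenerate quantiles: score is constant")
    ranks = stats.rankdata(s, method="average")
    dec = np.minimum(n_groups - 1, ((ranks - 0.5) / len(s) * n_groups).astype(int)) + 1
    return dec


def _or_from_counts(a, b, c, d, level=0.95, flags=None, n=None, model=""):
    """Log OR = ln(ad/bc) with Woolf SE; Haldane-Anscombe 0.5 on zero cells."""
    flags = list(flags or [])
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
        flags.append("zero-cell continuity correction")
    a_, b_, c_, d_ = cells
    est = float(np.log(a_ * d_ / (b_ * c_)))
    se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    z = stats.norm.isf((1 - level) / 2)
    p = float(2 * stats.norm.sf(abs(est / se)))
    return AssociationResult(
        estimate=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
        p=p, n=int(n if n is not None else cells.sum()), model=model, flags=flags,
    )


def decile_analysis(
    score,
    labels,
    reference: str = "decile1",
    level: float = 0.95,
) -> list[AssociationResult]:
    """Odds ratio of COPD for each score decile against a reference group.

    ``reference`` is ``decile1`` (lowest decile) or ``middle_tertile``.
    ORs come from the 2x2 case/control counts of each decile against the
    reference; zero cells receive the Haldane-Anscombe correction (flagged).
    """
    s = _score_array(score)
    y = np.asarray(labels, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(s)
    s, y = s[mask], y[mask]
    dec = assign_deciles(s)

    if reference == "decile1":
        ref_mask = dec == 1
        targets = range(2, 11)
    elif reference == "middle_tertile":
        tert = assign_deciles(s, n_groups=3)
        ref_mask = tert == 2
        targets = range(1, 11)
    else:
        raise ValueError("reference must be 'decile1' or 'middle_tertile'")
    ref_cases = int(y[ref_mask].sum())
    ref_ctrls = int((1 - y[ref_mask]).sum())

    results = []
    for d in targets:
        m = dec == d
        cases, ctrls = int(y[m].sum()), int((1 - y[m]).sum())
        if cases + ctrls == 0:
            raise ValueError(f"decile {d} is empty")
        res = _or_from_counts(
            cases, ctrls, ref_cases, ref_ctrls, level=level,
            n=int(m.sum() + ref_mask.sum()),
            model=f"decile{d} vs {reference}",
        )
        results.append(res)
    return results


def auc_models(
    ph: pd.DataFrame,
    score,
    covariate_sets: Mapping[str, Sequence[str]] | None = None,
    outcome: str = "copd",
    level: float = 0.95,
    n_subpopulations: int = 10,
) -> list[RocResult]:
    """AUC of fitted probabilities for each candidate model, with comparisons.

    Default models: the score alone; clinical risk factors (age, sex,
    pack-years) alone; clinical factors plus the score.  Each later model is
    compared to every earlier one by DeLong's correlated-ROC test.  The
    Bonferroni family threshold for ``n_subpopulations`` comparisons is
    reported on the result, not enforced.
    """
    if covariate_sets is None:
        covariate_sets = {
            "prs": ["__score__"],
            "clinical": ["age", "sex", "pack_years"],
            "clinical+prs": ["age", "sex", "pack_years", "__score__"],
        }
    s = _score_array(score)
    y = ph[outcome].to_numpy(dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(s)
    y = y[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    z = stats.norm.isf((1 - level) / 2)

    results: list[RocResult] = []
    probs: dict[str, np.ndarray] = {}
    for name, cols in covariate_sets.items():
        X = np.column_stack(
            [s[mask] if c == "__score__" else ph.loc[mask, c].to_numpy(dtype=float) for c in cols]
        )
        fit = _logistic(y, X, cols)
        p_hat = np.asarray(fit.predict())
        probs[name] = p_hat
        auc, var = delong_variance(y, p_hat)
        se = float(np.sqrt(var))
        comparisons = []
        for prev in results:
            delta, pval = delong_test(y, p_hat, probs[prev.model])
            comparisons.append((prev.model, float(delta), float(pval)))
        results.append(
            RocResult(
                auc=float(auc), se=se,
                ci_low=max(0.0, auc - z * se), ci_high=min(1.0, auc + z * se),
                curve=roc_curve_points(y, p_hat), model=name, comparisons=comparisons,
            )
        )
    logger.info("auc_models: Bonferroni threshold %.4g for %d subpopulations",
                0.05 / n_subpopulations, n_subpopulations)
    return results


def youden_and_metrics(labels, scores) -> ScreeningMetrics:
    """Cutoff maximizing Youden's J, with screening metrics at that cutoff.

    Ties on J are broken toward higher specificity (fewer false positives).
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("single class: cannot compute screening metrics")
    s = np.asarray(scores, dtype=float)
    pts = roc_curve_points(y, s)
    best = None
    n_ties = 0
    for sens, spec, thr in pts:
        j = sens + spec - 1
        key = (j, spec)
        if best is None or key > best[0]:
            best, n_ties = (key, (sens, spec, thr)), 0
        elif np.isclose(j, best[0][0]):
            n_ties += 1
    (j, _), (sens, spec, thr) = best
    pred = s >= thr
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    flags = ["youden tie broken toward higher specificity"] if n_ties else []
    return ScreeningMetrics(
        cutoff=float(thr), sensitivity=sens, specificity=spec,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        youden=float(j), flags=flags,
    )


def clinical_risk_score(
    train: pd.DataFrame,
    apply_to: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "pack_years"),
    outcome: str = "copd",
) -> tuple[dict, PRSProfile]:
    """Fit a clinical COPD risk model on one cohort and export its score.

    The linear predictor (frozen coefficients, no refitting) is evaluated on
    ``apply_to`` and returned as a standardized external score.
    """
    y = train[outcome].to_numpy(dtype=float)
    mask = ~np.isnan(y)
    X = train.loc[mask, list(covariates)].to_numpy(dtype=float)
    fit = _logistic(y[mask], X, covariates)
    params = {"const": float(fit.params[0])}
    params.update({c: float(fit.params[i + 1]) for i, c in enumerate(covariates)})
    Xa = apply_to[list(covariates)].to_numpy(dtype=float)
    raw = params["const"] + Xa @ np.array([params[c] for c in covariates])
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    sample_ids = apply_to["sample_id"] if "sample_id" in apply_to.columns else np.arange(len(apply_to))
    prof = PRSProfile(
        trait="CLINICAL", cohort="external",
        table=pd.DataFrame({"sample_id": sample_ids, "raw": raw, "std": std}),
        n_variants_used=0,
    )
    return params, prof


def exacerbation_models(
    ph: pd.DataFrame,
    score,
    outcomes: Sequence[str] = ("frequent_exacerbations", "severe_exacerbations"),
    base_covariates: Sequence[str] = ("age", "sex", "pack_years"),
    lung_function: Sequence[str] = ("fev1_pct_pred", "fev1_fvc"),
) -> dict[str, tuple[AssociationResult, AssociationResult]]:
    """Score-exacerbation associations, unadjusted and lung-function adjusted.

    For each outcome two logistic fits are reported: base covariates only,
    and base covariates plus baseline FEV1 %pred and FEV1/FVC.  If the
    genetic association with exacerbations runs through lung function, the
    adjusted estimate should attenuate toward zero.
    """
    missing = [c for c in lung_function if c not in ph.columns]
    if missing:
        raise ValueError(f"missing lung-function column(s) for adjusted model: {missing}")
    out = {}
    for outcome in outcomes:
        if outcome not in ph.columns:
            continue
        base = fit_or_per_sd(ph, score, covariates=base_covariates, outcome=outcome)
        adj = fit_or_per_sd(ph, score, covariates=tuple(base_covariates) + tuple(lung_function), outcome=outcome)
        out[outcome] = (base, adj)
    return out
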