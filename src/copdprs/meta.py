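"""Meta-analysis across cohorts and attributable-risk decomposition.

Per-cohort effect estimates (log-ORs per SD, AUCs, Tobit slopes) are pooled
with inverse-variance fixed effects, DerSimonian-Laird random effects, or —
for AUCs — effective-sample-size weighting with n_eff = 4/(1/n_cases +
1/n_controls).  Heterogeneity is summarized by Cochran's Q and I^2.

Smoking's contribution to COPD burden is quantified by attributable risk in
the exposed, AR% = 100*(RR-1)/RR, and Levin's population-attributable risk,
PAR% = 100*p_e*(RR-1)/(1 + p_e*(RR-1)), plus a targeted-intervention table:
the expected reduction in total cases from removing the exposure inside a
chosen score stratum (e.g. the top risk decile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetaResult",
    "RiskDecomposition",
    "meta_fixed_iv",
    "meta_random_dl",
    "effective_sample_size",
    "meta_ess_auc",
    "attributable_risk",
    "targeted_impact",
]


@dataclass
class MetaResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    Q: float
    I2: float          # percent, in [0, 100]
    tau2: float
    k: int
    weights: np.ndarray  # normalized, sum to 1

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.estimate / self.se)))


@dataclass
class RiskDecomposition:
    rr: float
    ar_pct: float
    par_pct: float
    p_exposed: float
    impact: pd.DataFrame | None = None  # per-stratum expected % reduction in cases


def _check_k(estimates, ses=None):
    est = np.asarray(estimates, dtype=float)
    if len(est) < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    if ses is not None:
        se = np.asarray(ses, dtype=float)
        if len(se) != len(est):
            raise ValueError("estimates and ses must have equal length")
        if (se <= 0).any():
            raise ValueError("standard errors must be positive")
        return est, se
    return est


def _heterogeneity(est, se):
    w = 1.0 / se**2
    pooled = (w * est).sum() / w.sum()
    Q = float((w * (est - pooled) ** 2).sum())
    k = len(est)
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100) if Q > 0 else 0.0
    return pooled, Q, I2, w


def meta_fixed_iv(estimates, ses, level: float = 0.95) -> MetaResult:
    """Inverse-variance fixed-effects pooling with Q and I^2."""
    est, se = _check_k(estimates, ses)
    pooled, Q, I2, w = _heterogeneity(est, se)
    se_pooled = float(1.0 / np.sqrt(w.sum()))
    z = stats.norm.isf((1 - level) / 2)
    return MetaResult(
        estimate=float(pooled), se=se_pooled,
        ci_low=pooled - z * se_pooled, ci_high=pooled + z * se_pooled,
        method="fixed_iv", Q=Q, I2=I2, tau2=0.0, k=len(est), weights=w / w.sum(),
    )


def meta_random_dl(estimates, ses, level: float = 0.95) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); with
    homogeneous studies (Q <= k-1) this reduces exactly to fixed effects.
    """
    est, se = _check_k(estimates, ses)
    _, Q, I2, w = _heterogeneity(est, se)
    k = len(est)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = float(max(0.0, (Q - (k - 1)) / denom)) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * est).sum() / w_star.sum())
    se_pooled = float(1.0 / np.sqrt(w_star.sum()))
    z = stats.norm.isf((1 - level) / 2)
    return MetaResult(
        estimate=pooled, se=se_pooled,
        ci_low=pooled - z * se_pooled, ci_high=pooled + z * se_pooled,
        method="random_dl", Q=Q, I2=I2, tau2=tau2, k=k, weights=w_star / w_star.sum(),
    )


def effective_sample_size(n_cases, n_controls):
    """Case-control effective sample size: 4 / (1/n_cases + 1/n_controls)."""
    n1 = np.asarray(n_cases, dtype=float)
    n0 = np.asarray(n_controls, dtype=float)
    if (n1 <= 0).any() or (n0 <= 0).any():
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n1 + 1.0 / n0)


def meta_ess_auc(aucs, n_cases, n_controls, ses=None, level: float = 0.95) -> MetaResult:
    """Effective-sample-size-weighted mean AUC.

    Weights are proportional to n_eff.  Per-study variances for the pooled SE
    use supplied (DeLong) SEs when given, else the Hanley-McNeil
    approximation from the case/control counts.
    """
    auc = _check_k(aucs)
    n_eff = effective_sample_size(n_cases, n_controls)
    if len(n_eff) != len(auc):
        raise ValueError("counts must match the number of AUCs")
    w = n_eff / n_eff.sum()
    pooled = float((w * auc).sum())
    if ses is not None:
        var = np.asarray(ses, dtype=float) ** 2
    else:
        # Hanley-McNeil variance of each study's AUC
        n1 = np.asarray(n_cases, dtype=float)
        n0 = np.asarray(n_controls, dtype=float)
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
        var = np.maximum(var, np.finfo(float).tiny)
    se_pooled = float(np.sqrt((w**2 * var).sum()))
    z = stats.norm.isf((1 - level) / 2)
    # heterogeneity on the inverse-variance scale for reference
    _, Q, I2, _ = _heterogeneity(auc, np.sqrt(var))
    return MetaResult(
        estimate=pooled, se=se_pooled,
        ci_low=pooled - z * se_pooled, ci_high=pooled + z * se_pooled,
        method="ess_weighted", Q=Q, I2=I2, tau2=0.0, k=len(auc), weights=w,
    )


def _risk_from_2x2(exposure: np.ndarray, outcome: np.ndarray):
    e = np.asarray(exposure, dtype=bool)
    y = np.asarray(outcome, dtype=float)
    if e.sum() == 0 or (~e).sum() == 0:
        raise ValueError("both exposed and unexposed groups must be non-empty")
    risk_e = y[e].mean()
    risk_u = y[~e].mean()
    return risk_e, risk_u, e, y


def attributable_risk(exposure, outcome) -> RiskDecomposition:
    """AR% and Levin PAR% for a binary exposure, cross-checked by counting.

    RR = risk_exposed / risk_unexposed; AR% = 100*(RR-1)/RR;
    PAR% = 100*p_e*(RR-1)/(1 + p_e*(RR-1)).  PAR% is also recomputed as the
    excess-case fraction (total cases minus cases expected at the unexposed
    rate, over total cases) and the two must agree.
    """
    risk_e, risk_u, e, y = _risk_from_2x2(exposure, outcome)
    if risk_u == 0:
        raise ValueError("unexposed risk is zero: RR undefined")
    rr = risk_e / risk_u
    ar_pct = 100.0 * (rr - 1.0) / rr
    p_e = e.mean()
    par_pct = 100.0 * p_e * (rr - 1.0) / (1.0 + p_e * (rr - 1.0))

    total_cases = y.sum()
    if total_cases > 0:
        par_count = 100.0 * (total_cases - len(y) * risk_u) / total_cases
        if not np.isclose(par_pct, par_count, rtol=1e-9, atol=1e-9):
            raise AssertionError(
                f"Levin PAR% {par_pct} disagrees with excess-case counting {par_count}"
            )
    return RiskDecomposition(rr=float(rr), ar_pct=float(ar_pct), par_pct=float(par_pct), p_exposed=float(p_e))


def targeted_impact(
    decile_assignment,
    exposure,
    outcome,
    strata: dict[str, list] | None = None,
    ar_pct: float | None = None,
) -> RiskDecomposition:
    """Expected % reduction in total cases from exposure removal per stratum.

    For each stratum (a set of deciles) the expected removed cases are the
    exposed cases in the stratum times AR%/100 (complete-efficacy
    assumption); the table reports this as a percent of all cases.  AR% is
    computed from the full data unless supplied.  A stratum with no exposed
    individuals has impact 0 (flagged).
    """
    dec = np.asarray(decile_assignment)
    e = np.asarray(exposure, dtype=bool)
    y = np.asarray(outcome, dtype=float)
    if not (len(dec) == len(e) == len(y)):
        raise ValueError("deciles, exposure and outcome must be aligned")
    base = attributable_risk(e, y) if ar_pct is None else None
    ar = base.ar_pct if base is not None else float(ar_pct)
    total_cases = y.sum()
    if total_cases == 0:
        raise ValueError("no cases in the data")
    if strata is None:
        strata = {"top_decile": [10], "bottom_decile": [1]}
        strata.update({f"decile{d}": [d] for d in range(1, 11)})
    rows = []
    for name, deciles in strata.items():
        m = np.isin(dec, deciles)
        exposed_cases = float((y[m & e]).sum())
        flag = ""
        if (m & e).sum() == 0:
            flag = "no exposed individuals in stratum"
        removed = exposed_cases * ar / 100.0
        rows.append(
            {"stratum": name, "exposed_cases": exposed_cases,
             "reduction_pct_of_cases": 100.0 * removed / total_cases, "flag": flag}
        )
    impact = pd.DataFrame(rows)
    return RiskDecomposition(
        rr=base.rr if base else np.nan,
        ar_pct=ar,
        par_pct=base.par_pct if base else np.nan,
        p_exposed=float(e.mean()),
        impact=impact,
    )
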