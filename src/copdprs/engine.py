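"""Derivation and application of the polygenic risk scores.

The score weights solve a lasso-type problem posed entirely in terms of GWAS
summary statistics and a reference LD matrix.  Writing r for the vector of
marginal SNP-trait correlations (recovered from p-values and effect signs)
and R for the block-diagonal LD correlation matrix, the weights minimize

    f(beta) = 1/2 beta' [(1-s) R + s I] beta - r' beta + lam * ||beta||_1

where s in (0, 1] shrinks the LD matrix toward the identity (s = 1 ignores
LD and reduces each coordinate to soft-thresholding of r).  Because the
regularized matrix has unit diagonal, coordinate descent takes the simple
form beta_j <- soft(r_j - (1-s) * sum_{k != j} R_jk beta_k, lam).

Hyperparameters (s, lam) are tuned on an independent cohort, individuals are
scored as the weighted dosage sum, scores are standardized within cohort,
and the two trait scores (FEV1, FEV1/FVC) are combined with logistic-
regression coefficients fitted against COPD status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .ld import LDBlocks
from .roc import mann_whitney_auc
from .simulate import GenotypeMatrix
from .sumstats import PRSWeights, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "TuningGrid",
    "PRSProfile",
    "CombinedModel",
    "ConvergenceError",
    "pvalue_to_correlation",
    "soft_threshold",
    "fit_sparse_weights",
    "derive_weights",
    "tune_hyperparameters",
    "score_individuals",
    "combine_scores",
]

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the last iterate."""

    def __init__(self, msg, beta=None, max_delta=None):
        super().__init__(msg)
        self.beta = beta
        self.max_delta = max_delta


@dataclass(frozen=True)
class TuningGrid:
    """Hyperparameter grid: shrinkage values and penalty values, ascending."""

    s_values: tuple = (0.2, 0.5, 0.9, 1.0)
    lambda_values: tuple = tuple(np.geomspace(0.001, 0.1, 20))
    metric: str = "trait_r2"  # or "copd_auc"

    def __post_init__(self):
        if not self.s_values or not self.lambda_values:
            raise ValueError("grid must be non-empty")
        if any(not (0 < s <= 1) for s in self.s_values):
            raise ValueError("s values must be in (0, 1]")
        if any(l <= 0 for l in self.lambda_values):
            raise ValueError("lambda values must be > 0")
        object.__setattr__(self, "s_values", tuple(sorted(self.s_values)))
        object.__setattr__(self, "lambda_values", tuple(sorted(self.lambda_values)))
        if self.metric not in ("trait_r2", "copd_auc"):
            raise ValueError("metric must be 'trait_r2' or 'copd_auc'")


@dataclass
class PRSProfile:
    """Per-individual raw and within-cohort-standardized scores."""

    trait: str
    cohort: str
    table: pd.DataFrame  # columns: sample_id, raw, std
    n_variants_used: int = 0

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw"].to_numpy()

    @property
    def std(self) -> np.ndarray:
        return self.table["std"].to_numpy()

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])


@dataclass
class CombinedModel:
    """Coefficients combining the FEV1 and FEV1/FVC scores into one score."""

    b_fev1: float
    b_ratio: float
    intercept: float = 0.0
    source: str = ""

    def __post_init__(self):
        if not all(np.isfinite([self.b_fev1, self.b_ratio, self.intercept])):
            raise ValueError("combined-model coefficients must be finite")


def pvalue_to_correlation(p, sign_of_beta, n):
    """Recover the marginal SNP-trait correlation from a two-sided p-value.

    r = sign * |t| / sqrt(n - 2 + t^2) with t the upper-tail t quantile at
    p/2 on n-2 degrees of freedom.  Vectorized over variants.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise ValueError("n must be >= 3 to recover a correlation")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    t = stats.t.isf(p / 2, df=n - 2)
    r = np.sign(np.asarray(sign_of_beta, dtype=float)) * t / np.sqrt(n - 2 + t**2)
    return r if r.ndim else float(r)


def soft_threshold(z, lam):
    """soft(z, lam) = sign(z) * max(|z| - lam, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def _cd_block(R: np.ndarray, r: np.ndarray, s: float, lam: float, beta0, tol, max_iter):
    """Coordinate descent on one LD block; returns (beta, n_iter)."""
    k = len(r)
    beta = np.zeros(k) if beta0 is None else beta0.astype(float).copy()
    c = 1.0 - s
    if c == 0.0:
        return soft_threshold(r, lam), 1
    Rb = R @ beta
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(k):
            z = r[j] - c * (Rb[j] - beta[j])
            new = soft_threshold(z, lam)
            d = new - beta[j]
            if d != 0.0:
                Rb += R[:, j] * d
                beta[j] = new
                max_delta = max(max_delta, abs(d))
        if max_delta < tol:
            return beta, it + 1
    raise ConvergenceError(
        f"coordinate descent did not converge in {max_iter} iterations (max|dbeta|={max_delta:.2e})",
        beta=beta, max_delta=max_delta,
    )


def fit_sparse_weights(
    r: np.ndarray,
    ld: LDBlocks,
    s: float,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Minimize the penalized summary-statistic objective by block CD.

    ``r`` must be aligned with the concatenated variant order of ``ld``.
    Returns the full (dense) weight vector; zeros mark excluded variants.
    """
    if not (0 < s <= 1):
        raise ValueError("s must be in (0, 1]")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    r = np.asarray(r, dtype=float)
    if len(r) != ld.m:
        raise ValueError(f"r has {len(r)} entries but LD blocks cover {ld.m} variants")
    beta = np.empty_like(r)
    for block, sl in ld.block_slices():
        b0 = None if beta0 is None else beta0[sl]
        beta[sl], _ = _cd_block(block.R, r[sl], s, lam, b0, tol, max_iter)
    return beta


def _align_sumstats_to_ld(ss: SummaryStats, ld: LDBlocks) -> pd.DataFrame:
    order = ld.variant_ids
    tab = ss.table.set_index("id")
    missing = [v for v in order if v not in tab.index]
    if missing:
        raise ValueError(f"{len(missing)} LD variants missing from summary stats (e.g. {missing[:3]})")
    return tab.loc[order].reset_index()


def derive_weights(ss: SummaryStats, ld: LDBlocks, s: float, lam: float, **cd_kwargs) -> PRSWeights:
    """Full derivation: p-values -> correlations -> penalized weights."""
    tab = _align_sumstats_to_ld(ss, ld)
    r = pvalue_to_correlation(tab["p"].to_numpy(), np.sign(tab["beta"].to_numpy()), tab["n"].to_numpy())
    beta = fit_sparse_weights(r, ld, s, lam, **cd_kwargs)
    out = pd.DataFrame(
        {
            "id": tab["id"],
            "chrom": tab["chrom"].astype(str),
            "pos": tab["pos"],
            "effect_allele": tab["effect_allele"],
            "weight": beta,
        }
    )
    return PRSWeights(trait=ss.trait, s=s, lam=lam, table=out)


def tune_hyperparameters(
    ss: SummaryStats,
    ld: LDBlocks,
    tuning_genotypes: GenotypeMatrix,
    tuning_phenotypes: pd.DataFrame,
    grid: TuningGrid,
    trait_column: str = "fev1_pct_pred",
    cohort: str = "tuning",
) -> tuple[PRSWeights, pd.DataFrame]:
    """Select (s, lambda) maximizing the tuning metric on an external cohort.

    For every grid point the weights are refit (warm-started along the
    descending-lambda path within each s), the tuning cohort is scored, and
    the metric — squared correlation with the trait, or AUC against COPD —
    is evaluated.  Exact metric ties resolve toward larger lambda (sparser
    model).  Returns the winning weights and the full grid report.
    """
    tab = _align_sumstats_to_ld(ss, ld)
    r = pvalue_to_correlation(tab["p"].to_numpy(), np.sign(tab["beta"].to_numpy()), tab["n"].to_numpy())
    if grid.metric == "trait_r2":
        target = tuning_phenotypes[trait_column].to_numpy(dtype=float)
    else:
        target = tuning_phenotypes["copd"].to_numpy(dtype=float)
        if len(np.unique(target[~np.isnan(target)])) < 2:
            raise ValueError("copd_auc metric requires both outcome classes in the tuning cohort")

    rows = []
    best = None  # (metric, lam, s, beta)
    any_defined = False
    for s in grid.s_values:
        warm = None
        for lam in sorted(grid.lambda_values, reverse=True):
            beta = fit_sparse_weights(r, ld, s, lam, beta0=warm)
            warm = beta
            w = PRSWeights(
                trait=ss.trait, s=s, lam=lam,
                table=pd.DataFrame(
                    {"id": tab["id"], "chrom": tab["chrom"].astype(str), "pos": tab["pos"],
                     "effect_allele": tab["effect_allele"], "weight": beta}
                ),
            )
            n_nonzero = int((beta != 0).sum())
            if n_nonzero == 0:
                metric = np.nan
            else:
                prof = score_individuals(tuning_genotypes, w, cohort=cohort)
                scores = prof.raw
                if np.std(scores) == 0:
                    metric = np.nan
                elif grid.metric == "trait_r2":
                    metric = float(np.corrcoef(scores, target)[0, 1] ** 2)
                else:
                    # discrimination is what matters for ranking
                    # hyperparameters; a lung-function score is protective
                    # for COPD, so fold the AUC about 0.5
                    auc = mann_whitney_auc(target, scores)
                    metric = float(max(auc, 1 - auc))
            rows.append({"s": s, "lam": lam, "metric": metric, "n_nonzero": n_nonzero})
            if np.isfinite(metric):
                any_defined = True
                key = (metric, lam)  # ties -> larger lambda
                if best is None or key > (best[0], best[1]):
                    best = (metric, lam, s, beta.copy())
    if not any_defined:
        raise ValueError("tuning metric undefined (constant scores) at every grid point")
    report = pd.DataFrame(rows)
    metric_val, lam, s, beta = best
    logger.info("tuning selected s=%g lambda=%g (%s=%.4f)", s, lam, grid.metric, metric_val)
    winner = PRSWeights(
        trait=ss.trait, s=s, lam=lam,
        table=pd.DataFrame(
            {"id": tab["id"], "chrom": tab["chrom"].astype(str), "pos": tab["pos"],
             "effect_allele": tab["effect_allele"], "weight": beta}
        ),
    )
    return winner, report


def score_individuals(G: GenotypeMatrix, w: PRSWeights, cohort: str = "") -> PRSProfile:
    """Apply weights to a cohort: raw weighted dosage sum, then standardize.

    Variants are matched by id; when the weight's effect allele matches the
    cohort's *other* allele the dosage is complemented (2 - d).  Missing
    dosages are mean-imputed from the cohort itself.  Raises if no weight
    variant overlaps the cohort.
    """
    pos_by_id = {v.id: j for j, v in enumerate(G.variants)}
    cols, wvec = [], []
    flip = []
    for row in w.table.itertuples(index=False):
        j = pos_by_id.get(row.id)
        if j is None:
            continue
        v = G.variants[j]
        if row.effect_allele == v.effect_allele:
            flip.append(False)
        elif row.effect_allele == v.other_allele:
            flip.append(True)
        else:
            logger.warning("score_individuals: allele mismatch at %s, skipped", row.id)
            continue
        cols.append(j)
        wvec.append(row.weight)
    if not cols:
        raise ValueError("no overlapping variants between weights and cohort")
    D = G.dosages[:, cols].astype(float).copy()
    if np.isnan(D).any():
        mu = np.nanmean(D, axis=0)
        idx = np.nonzero(np.isnan(D))
        D[idx] = np.take(mu, idx[1])
    flip = np.asarray(flip)
    if flip.any():
        D[:, flip] = 2.0 - D[:, flip]
    raw = D @ np.asarray(wvec)
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    tab = pd.DataFrame({"sample_id": G.sample_ids, "raw": raw, "std": std})
    return PRSProfile(trait=w.trait, cohort=cohort, table=tab, n_variants_used=len(cols))


def combine_scores(
    prs_fev1: PRSProfile,
    prs_ratio: PRSProfile,
    labels=None,
    mode: str = "fitted",
    coefficients: tuple[float, float] | None = None,
) -> tuple[CombinedModel, PRSProfile]:
    """Combine the two trait scores into a single COPD score.

    ``fitted``: logistic regression of COPD on the two standardized scores;
    the coefficients weight the combination.  ``unweighted``: simple sum.
    ``fixed``: apply supplied ``coefficients``.  The combined profile is
    re-standardized within the cohort.
    """
    if prs_fev1.sample_ids != prs_ratio.sample_ids:
        raise ValueError("profiles are not aligned on the same samples")
    s1, s2 = prs_fev1.std, prs_ratio.std
    if mode == "fitted":
        y = np.asarray(labels, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("fitted mode requires both COPD classes")
        if abs(np.corrcoef(s1, s2)[0, 1]) > 0.9999:
            warnings.warn("input scores are collinear; splitting a single-score coefficient")
            fit = sm.Logit(y, sm.add_constant(s1)).fit(disp=0)
            model = CombinedModel(b_fev1=fit.params[1] / 2, b_ratio=fit.params[1] / 2,
                                  intercept=fit.params[0], source=prs_fev1.cohort)
        else:
            X = sm.add_constant(np.column_stack([s1, s2]))
            fit = sm.Logit(y, X).fit(disp=0)
            model = CombinedModel(b_fev1=fit.params[1], b_ratio=fit.params[2],
                                  intercept=fit.params[0], source=prs_fev1.cohort)
    elif mode == "unweighted":
        model = CombinedModel(b_fev1=1.0, b_ratio=1.0, source=prs_fev1.cohort)
    elif mode == "fixed":
        if coefficients is None:
            raise ValueError("fixed mode requires coefficients=(b_fev1, b_ratio)")
        model = CombinedModel(b_fev1=coefficients[0], b_ratio=coefficients[1], source="fixed")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    raw = model.b_fev1 * s1 + model.b_ratio * s2
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    tab = pd.DataFrame({"sample_id": prs_fev1.sample_ids, "raw": raw, "std": std})
    nvar = max(prs_fev1.n_variants_used, prs_ratio.n_variants_used)
    prof = PRSProfile(trait="COMBINED", cohort=prs_fev1.cohort, table=tab, n_variants_used=nvar)
    return model, prof
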