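"""Synthetic cohorts with LD-blocked genotypes and polygenic lung function.

Everything downstream of a real GWAS — weight derivation, scoring, cohort
evaluation, meta-analysis — needs genotypes with linkage disequilibrium,
additively polygenic FEV1 and FEV1/FVC with chosen heritabilities and genetic
correlation, spirometric disease categories, smoking exposure, and secondary
phenotypes (exacerbations, CT imaging measures, lung-growth patterns).  This
module generates all of it reproducibly so the pipeline can be exercised and
validated end-to-end without any cohort download.

Genotype model: each haplotype is a thresholded latent Gaussian with
first-order autoregressive correlation ``within_block_rho`` inside fixed-size
blocks and zero correlation across blocks; a dosage is the sum of two
independent haplotypes, so it lies in {0, 1, 2}.

Phenotype model: a sparse set of causal variants receives bivariate Gaussian
effects (correlation ``genetic_corr`` between the FEV1 and FEV1/FVC effects).
Each standardized trait is genetic score + environment, with the genetic part
scaled to the target heritability.  Smoking (pack-years) contributes a fixed
share of the environmental variance, so the genetic score stays uncorrelated
with pack-years while heavier smokers still have worse lung function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "ConfigurationError",
    "GOLD_CATEGORIES",
    "simulate_ld_genotypes",
    "simulate_lung_phenotypes",
    "assign_gold_categories",
    "simulate_downstream_phenotypes",
    "simulate_gwas_sumstats",
    "simulate_cohort",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes_tsv",
]

GOLD_CATEGORIES = ["PRISm", "GOLD0", "GOLD1", "GOLD2", "GOLD3", "GOLD4"]

GROWTH_PATTERNS = ["normal-normal", "normal-early", "reduced-normal", "reduced-early"]

#: non-palindromic allele pairs cycled over simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults approximate a smoking-enriched case-control cohort: ~1000-variant
    genome in 10-variant LD blocks, heritabilities 0.4 for both lung-function
    traits, genetic correlation 0.7 between them, 20% of variants causal.
    """

    n_individuals: int = 2000
    n_variants: int = 1000
    block_size: int = 10
    within_block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_fev1: float = 0.4
    h2_ratio: float = 0.4
    genetic_corr: float = 0.7
    prop_causal: float = 0.2
    seed: int = 0
    #: seed for the shared genetic architecture (causal variants, effect
    #: sizes, allele frequencies); cohorts of one study share it while their
    #: individual-level seeds differ.  None -> derived from ``seed``.
    architecture_seed: int | None = None
    # phenotype-scale parameters (see docs/methods.md)
    fev1_pct_mean: float = 90.0
    fev1_pct_sd: float = 13.0
    ratio_mean: float = 0.73
    ratio_sd: float = 0.06
    env_corr: float = 0.3
    smoking_env_share: float = 0.2
    n_pcs: int = 5
    # configurable linear reference equation for absolute predicted FEV1 (L):
    # intercept + b_height*height_cm + b_age*age_years + b_sex*sex
    ref_eq: tuple[float, float, float, float] = (-2.0, 0.035, -0.025, -0.6)

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_variants < 1 or self.block_size < 1:
            raise ConfigurationError("counts must be positive")
        if not (0 <= self.within_block_rho < 1):
            raise ConfigurationError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("h2_fev1", "h2_ratio"):
            if not (0 <= getattr(self, name) < 1):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if not (-1 <= self.genetic_corr <= 1):
            raise ConfigurationError("genetic_corr must be in [-1, 1]")
        if not (0 < self.prop_causal <= 1):
            raise ConfigurationError("prop_causal must be in (0, 1]")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")

    @property
    def arch_seed(self) -> int:
        return self.seed if self.architecture_seed is None else self.architecture_seed


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n individuals x m variants) with variant metadata."""

    dosages: np.ndarray
    sample_ids: list
    variants: list  # list[VariantRecord], aligned with columns

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.variants) != m:
            raise ValueError("dosage shape inconsistent with sample/variant lists")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list:
        return [v.id for v in self.variants]


def _block_slices(m: int, block_size: int):
    return [slice(i, min(i + block_size, m)) for i in range(0, m, block_size)]


def _latent_haplotypes(rng, n, m, rho, block_size):
    """Latent AR(1)-within-block Gaussians; last block may be short."""
    z = np.empty((n, m))
    for sl in _block_slices(m, block_size):
        k = sl.stop - sl.start
        e = rng.standard_normal((n, k))
        z[:, sl.start] = e[:, 0]
        for j in range(1, k):
            z[:, sl.start + j] = rho * z[:, sl.start + j - 1] + np.sqrt(1 - rho**2) * e[:, j]
    return z


def simulate_ld_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw dosages as the sum of two thresholded latent-Gaussian haplotypes.

    Adjacent variants inside a block have latent correlation
    ``within_block_rho``; variants in different blocks are independent.  The
    minor-allele frequency of each variant is drawn uniformly from
    ``maf_range`` and realized by thresholding the latent Gaussian at its
    normal quantile.
    """
    rng = np.random.default_rng(cfg.seed)
    arch_rng = np.random.default_rng(cfg.arch_seed)
    n, m = cfg.n_individuals, cfg.n_variants
    mafs = arch_rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)
    h1 = _latent_haplotypes(rng, n, m, cfg.within_block_rho, cfg.block_size)
    h2 = _latent_haplotypes(rng, n, m, cfg.within_block_rho, cfg.block_size)
    dosages = (h1 < thresholds).astype(float) + (h2 < thresholds).astype(float)
    variants = []
    for j in range(m):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            VariantRecord(
                id=f"var{j:06d}",
                chrom=str(1 + j // 100000),
                pos=1000 * (j % 100000) + 1,
                effect_allele=ea,
                other_allele=oa,
            )
        )
    sample_ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variants=variants)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def simulate_lung_phenotypes(G: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Generate polygenic FEV1 %pred and FEV1/FVC plus covariates.

    Returns a phenotype table with one row per individual.  True genetic
    scores (``true_score_fev1``, ``true_score_ratio``) are retained so that
    tests can measure realized heritability and score recovery; a real cohort
    would not have them.
    """
    if G.n == 0 or G.m == 0:
        raise ConfigurationError("genotype matrix is empty")
    if cfg.h2_fev1 >= 1 or cfg.h2_ratio >= 1:
        raise ConfigurationError("heritability must be < 1")
    rng = np.random.default_rng(cfg.seed + 1)
    n, m = G.n, G.m

    # sparse bivariate-Gaussian causal effects: drawn from the architecture
    # seed so every cohort of a study shares the same genetic model
    arch_rng = np.random.default_rng(cfg.arch_seed + 1)
    n_causal = max(1, int(round(cfg.prop_causal * m)))
    causal_idx = arch_rng.choice(m, size=n_causal, replace=False)
    cov = np.array([[1.0, cfg.genetic_corr], [cfg.genetic_corr, 1.0]])
    eff = arch_rng.multivariate_normal(np.zeros(2), cov, size=n_causal)

    Z = _standardize_columns(G.dosages)
    g = Z[:, causal_idx] @ eff  # n x 2 raw genetic scores
    g = _standardize_columns(g)
    g_fev1 = np.sqrt(cfg.h2_fev1) * g[:, 0]
    g_ratio = np.sqrt(cfg.h2_ratio) * g[:, 1]

    # covariates
    sex = rng.integers(0, 2, size=n)  # female = 1
    age = rng.normal(60, 9, size=n).clip(35, 90)
    height = np.where(sex == 1, rng.normal(163, 6, size=n), rng.normal(177, 7, size=n))
    ever = rng.random(n) > 0.3
    pack_years = np.where(ever, rng.gamma(2.0, 15.0, size=n), 0.0)
    pcs = rng.standard_normal((n, cfg.n_pcs)) if cfg.n_pcs else np.zeros((n, 0))

    # environment: shared component + smoking + residual, scaled to 1 - h2
    z_smk = (pack_years - pack_years.mean()) / (pack_years.std() or 1.0)
    shared = rng.standard_normal(n)
    env = {}
    for trait, h2 in (("fev1", cfg.h2_fev1), ("ratio", cfg.h2_ratio)):
        e_var = 1.0 - h2
        b_smk = -np.sqrt(cfg.smoking_env_share * e_var)
        resid_var = e_var * (1 - cfg.smoking_env_share)
        a = np.sqrt(cfg.env_corr * resid_var)
        b = np.sqrt((1 - cfg.env_corr) * resid_var)
        env[trait] = b_smk * z_smk + a * shared + b * rng.standard_normal(n)

    z_fev1 = g_fev1 + env["fev1"]
    z_ratio = g_ratio + env["ratio"]

    fev1_pct_pred = cfg.fev1_pct_mean + cfg.fev1_pct_sd * z_fev1
    fev1_fvc = np.clip(cfg.ratio_mean + cfg.ratio_sd * z_ratio, 0.2, 0.95)
    c0, ch, ca, cs = cfg.ref_eq
    fev1_pred_l = c0 + ch * height + ca * age + cs * sex
    fev1_l = fev1_pred_l * fev1_pct_pred / 100.0

    ph = pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "age": age,
            "sex": sex,
            "height": height,
            "pack_years": pack_years,
            "fev1_pct_pred": fev1_pct_pred,
            "fev1_fvc": fev1_fvc,
            "fev1_l": fev1_l,
            "true_score_fev1": g_fev1,
            "true_score_ratio": g_ratio,
        }
    )
    for k in range(cfg.n_pcs):
        ph[f"pc{k + 1}"] = pcs[:, k]
    return assign_gold_categories(ph)


def assign_gold_categories(ph: pd.DataFrame) -> pd.DataFrame:
    """Assign the COPD flag and GOLD/PRISm spirometric category.

    Moderate-to-severe COPD: FEV1/FVC < 0.7 and FEV1 < 80% predicted.
    PRISm: FEV1/FVC >= 0.7 with FEV1 < 80% predicted.  With obstruction
    (ratio < 0.7) the grade follows FEV1 %pred: >=80 GOLD1, 50-79 GOLD2,
    30-49 GOLD3, <30 GOLD4.  Records missing spirometry are flagged
    (``spirometry_missing``) and left unlabeled.
    """
    for col in ("fev1_pct_pred", "fev1_fvc"):
        if col not in ph.columns:
            raise ValueError(f"missing spirometry column {col}")
    ph = ph.copy()
    pct = ph["fev1_pct_pred"].to_numpy(dtype=float)
    ratio = ph["fev1_fvc"].to_numpy(dtype=float)
    missing = np.isnan(pct) | np.isnan(ratio)
    obstructed = ratio < 0.7

    cat = np.full(len(ph), "", dtype=object)
    cat[~obstructed & (pct >= 80)] = "GOLD0"
    cat[~obstructed & (pct < 80)] = "PRISm"
    cat[obstructed & (pct >= 80)] = "GOLD1"
    cat[obstructed & (pct >= 50) & (pct < 80)] = "GOLD2"
    cat[obstructed & (pct >= 30) & (pct < 50)] = "GOLD3"
    cat[obstructed & (pct < 30)] = "GOLD4"
    cat[missing] = None

    copd = (obstructed & (pct < 80)).astype(float)
    copd[missing] = np.nan
    ph["copd"] = copd
    ph["gold_category"] = cat
    ph["spirometry_missing"] = missing
    if missing.any():
        logger.warning("assign_gold_categories: %d record(s) missing spirometry", int(missing.sum()))
    return ph


def simulate_downstream_phenotypes(
    ph: pd.DataFrame, prs_link: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Generate exacerbations, CT imaging phenotypes and growth patterns.

    A latent disease-severity variable correlates with the genetic liability
    (the negative of the standardized ``true_score_fev1``, so higher severity
    goes with genetically worse lung function) by ``prs_link``; the imaging
    phenotypes are linear, zero-censored, ordinal or categorical functions of
    it.  Exacerbations depend on lung function only (a mediated pathway), so
    genetic associations with exacerbations should vanish after adjusting for
    FEV1 and FEV1/FVC.
    """
    if not (-1 <= prs_link <= 1):
        raise ConfigurationError("prs_link must be in [-1, 1]")
    if "copd" not in ph.columns:
        raise ValueError("COPD labels must be assigned first")
    rng = np.random.default_rng(seed)
    ph = ph.copy()
    n = len(ph)
    gs = ph["true_score_fev1"].to_numpy(dtype=float)
    sd = gs.std() or 1.0
    gz = (gs - gs.mean()) / sd
    latent = prs_link * (-gz) + np.sqrt(1 - prs_link**2) * rng.standard_normal(n)

    # exacerbations: logistic in (low) lung function only
    z_pct = -(ph["fev1_pct_pred"] - ph["fev1_pct_pred"].mean()) / ph["fev1_pct_pred"].std()
    z_rat = -(ph["fev1_fvc"] - ph["fev1_fvc"].mean()) / ph["fev1_fvc"].std()
    lin = -1.6 + 1.0 * z_pct + 0.5 * z_rat
    ph["frequent_exacerbations"] = rng.binomial(1, 1 / (1 + np.exp(-lin)))
    lin_sev = -2.2 + 1.0 * z_pct + 0.5 * z_rat
    ph["severe_exacerbations"] = rng.binomial(1, 1 / (1 + np.exp(-lin_sev)))

    # continuous imaging measures
    ph["wap_pct"] = 50 + 4 * latent + 3 * rng.standard_normal(n)
    ph["pi10"] = 3.7 + 0.1 * latent + 0.08 * rng.standard_normal(n)
    ph["laa950_pct"] = np.exp(1.0 + 0.5 * latent + 0.4 * rng.standard_normal(n))
    ph["perc15"] = -910 - 15 * latent + 12 * rng.standard_normal(n)
    ph["gas_trapping_pct"] = np.exp(2.5 + 0.4 * latent + 0.35 * rng.standard_normal(n))

    # local-histogram emphysema percentages: left-censored at zero
    for pat, (mu, b) in {
        "lh_normal_pct": (60.0, -5.0),
        "lh_panlobular_pct": (0.0, 1.0),
        "lh_centrilobular_pct": (1.0, 2.0),
    }.items():
        lat = mu + b * latent + 2.0 * rng.standard_normal(n)
        ph[pat] = np.maximum(lat, 0.0)

    # visual emphysema grade (0-4, ordinal) and CT subtype
    vis = latent + rng.standard_normal(n)
    ph["visual_emphysema_grade"] = np.digitize(vis, [-0.5, 0.5, 1.5, 2.5])
    sub_lat = latent + rng.standard_normal(n)
    ph["ct_subtype"] = np.digitize(sub_lat, [0.3, 1.0, 1.8]) + 1  # 1 = normal imaging

    # lung growth: reduced-growth latent loads on the FEV1 causal effects
    growth = 0.4 * gz + np.sqrt(1 - 0.4**2) * rng.standard_normal(n)
    decline = rng.standard_normal(n)
    reduced = growth < -0.6
    early = decline < -0.3
    labels = np.where(
        reduced,
        np.where(early, "reduced-early", "reduced-normal"),
        np.where(early, "normal-early", "normal-normal"),
    )
    ph["growth_pattern"] = labels
    ph["bronchodilator_response"] = rng.normal(8, 4, size=n)
    ph["airway_hyperresponsiveness"] = rng.binomial(1, 0.4, size=n)
    return ph


def simulate_gwas_sumstats(G_train: GenotypeMatrix, trait: np.ndarray, trait_name: str = "FEV1") -> SummaryStats:
    """Per-variant simple-regression GWAS of a standardized trait.

    Each variant's beta/SE/p come from the marginal regression of the
    standardized trait on its dosage; signs follow the effect-allele coding of
    the genotype matrix.  Constant dosage columns are emitted with beta 0 and
    p 1 and flagged in the log.
    """
    n = G_train.n
    if n < 50:
        raise ConfigurationError("training GWAS requires n >= 50")
    y = np.asarray(trait, dtype=float)
    y = (y - y.mean()) / y.std()
    X = G_train.dosages
    xc = X - X.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ (y - y.mean())
    syy = ((y - y.mean()) ** 2).sum()

    const = sxx == 0
    if const.any():
        logger.warning("simulate_gwas_sumstats: %d constant genotype column(s)", int(const.sum()))
    sxx_safe = np.where(const, 1.0, sxx)
    beta = np.where(const, 0.0, sxy / sxx_safe)
    rss = syy - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(np.where(const, np.nan, sigma2 / sxx_safe))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(const, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))

    tab = pd.DataFrame(
        {
            "id": [v.id for v in G_train.variants],
            "chrom": [v.chrom for v in G_train.variants],
            "pos": [v.pos for v in G_train.variants],
            "effect_allele": [v.effect_allele for v in G_train.variants],
            "other_allele": [v.other_allele for v in G_train.variants],
            "beta": beta,
            "se": np.where(const, np.nan, se),
            "p": p,
            "n": n,
            "flagged_constant": const,
        }
    )
    return SummaryStats(trait=trait_name, table=tab)


def simulate_cohort(cfg: SimConfig, prs_link: float = 0.3) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Convenience: genotypes + full phenotype table for one cohort."""
    G = simulate_ld_genotypes(cfg)
    ph = simulate_lung_phenotypes(G, cfg)
    ph = simulate_downstream_phenotypes(ph, prs_link=prs_link, seed=cfg.seed + 2)
    return G, ph


# ---------------------------------------------------------------------------
# plain-text export

def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """Dosage matrix as TSV: variant metadata columns then one column per sample."""
    meta = pd.DataFrame(
        {
            "id": [v.id for v in G.variants],
            "chrom": [v.chrom for v in G.variants],
            "pos": [v.pos for v in G.variants],
            "effect_allele": [v.effect_allele for v in G.variants],
            "other_allele": [v.other_allele for v in G.variants],
        }
    )
    dos = pd.DataFrame(G.dosages.T, columns=G.sample_ids)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> GenotypeMatrix:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "effect_allele", "other_allele"]
    variants = [
        VariantRecord(id=r.id, chrom=r.chrom, pos=int(r.pos), effect_allele=r.effect_allele, other_allele=r.other_allele)
        for r in t[meta_cols].itertuples(index=False)
    ]
    sample_ids = [c for c in t.columns if c not in meta_cols]
    dosages = t[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, variants=variants)


def write_phenotypes_tsv(ph: pd.DataFrame, path) -> None:
    ph.to_csv(path, sep="\t", index=False)
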