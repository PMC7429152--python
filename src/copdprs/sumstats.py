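"""Reading, writing and harmonizing GWAS summary statistics and PRS weight files.

Summary statistics are the per-variant marginal effects from a lung-function
GWAS (effect size, standard error, p-value, sample size).  They are the raw
material for the penalized-regression weights.  Before weights can be applied
across cohorts, the effect-allele coding of every variant must be reconciled
with the reference panel and with each target cohort ("harmonization"), and
variants that are poorly imputed in any evaluation cohort are removed.

Canonical summary-statistic TSV columns: ``SNP CHR BP A1 A2 BETA SE P N``
(A1 is the effect allele).  Other dialects are supported via ``column_map``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "SummaryStats",
    "PRSWeights",
    "HarmonizationReport",
    "SumstatsFormatError",
    "read_sumstats",
    "filter_by_imputation",
    "harmonize_alleles",
    "write_weights",
    "read_weights",
]

#: canonical column -> internal name
CANONICAL_COLUMNS = {
    "SNP": "id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "N": "n",
}

_PALINDROMIC = ({"A", "T"}, {"C", "G"})

WEIGHTS_FORMAT_VERSION = "1"


class SumstatsFormatError(ValueError):
    """Raised for malformed summary-statistic or weight files."""


@dataclass(frozen=True)
class VariantRecord:
    """A single variant: identifier, location and allele coding.

    ``imputation_r2`` maps cohort name -> imputation quality R^2; a cohort in
    ``genotyped`` was directly genotyped there (no imputation needed).
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    imputation_r2: Mapping[str, float] = field(default_factory=dict)
    genotyped: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(f"variant {self.id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1")

    @property
    def allele_set(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return self.allele_set in _PALINDROMIC

    @property
    def key(self) -> tuple:
        """Matching key: chromosome, position, unordered allele pair."""
        return (self.chrom, self.pos, self.allele_set)


@dataclass
class SummaryStats:
    """Per-variant GWAS effects for one trait.

    ``table`` columns: id, chrom, pos, effect_allele, other_allele, beta, se,
    p, n.  One row per variant id; p in (0, 1]; se > 0.
    """

    trait: str
    table: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        t = self.table
        required = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "n"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SumstatsFormatError(f"missing required columns: {missing}")
        dup = t["id"][t["id"].duplicated()]
        if len(dup):
            raise SumstatsFormatError(f"duplicated variant id(s): {sorted(set(dup))[:5]}")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise SumstatsFormatError("p-values must lie in (0, 1]")
        if (t["se"].dropna() <= 0).any():
            raise SumstatsFormatError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list:
        return list(self.table["id"])


@dataclass
class PRSWeights:
    """Sparse per-variant weights defining a polygenic risk score.

    Only variants with non-zero weight are stored.  ``s`` is the LD shrinkage
    (s = 1 ignores LD entirely) and ``lam`` the lasso penalty under which the
    weights were derived.
    """

    trait: str
    s: float
    lam: float
    table: pd.DataFrame  # columns: id, chrom, pos, effect_allele, weight

    def __post_init__(self):
        if not (0 < self.s <= 1):
            raise ValueError("shrinkage s must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        nz = self.table["weight"] != 0
        if not nz.all():
            self.table = self.table.loc[nz].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PRSWeights):
            return NotImplemented
        return (
            self.trait == other.trait
            and self.s == other.s
            and self.lam == other.lam
            and self.table.reset_index(drop=True).equals(other.table.reset_index(drop=True))
        )


@dataclass
class HarmonizationReport:
    """Counts of what harmonization did to each class of variant."""

    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_palindromic_dropped: int = 0
    n_unmatched_dropped: int = 0
    n_mismatched_dropped: int = 0


def read_sumstats(path, trait: str = "FEV1", column_map: Mapping[str, str] | None = None) -> SummaryStats:
    """Read a summary-statistic TSV, validating and counting malformed rows.

    ``column_map`` maps file column names to canonical names (SNP, CHR, BP,
    A1, A2, BETA, SE, P, N) for non-canonical dialects.  Rows with
    non-positive p are rejected (counted and logged); a missing required
    column or a duplicated variant id is an error.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required column(s) {missing}")
    t = raw.rename(columns=CANONICAL_COLUMNS)
    t["chrom"] = t["chrom"].astype(str)

    bad_p = (t["p"] <= 0) | (t["p"] > 1) | t["p"].isna()
    if bad_p.any():
        logger.warning("%s: rejected %d row(s) with nonpositive p", path, int(bad_p.sum()))
        t = t.loc[~bad_p]
    dup = t["id"][t["id"].duplicated()]
    if len(dup):
        raise SumstatsFormatError(f"{path}: duplicated variant id(s): {sorted(set(dup))[:5]}")
    return SummaryStats(trait=trait, table=t.reset_index(drop=True))


def filter_by_imputation(
    ss: SummaryStats,
    cohort_r2: Mapping[str, pd.DataFrame],
    threshold: float = 0.5,
) -> SummaryStats:
    """Keep variants genotyped or well imputed (R^2 > threshold) in every cohort.

    ``cohort_r2`` maps cohort name -> table with columns ``id`` and ``r2``
    and/or a boolean ``genotyped`` column.  A variant absent from a cohort's
    table is treated as failing there (logged).
    """
    keep = pd.Series(True, index=ss.table["id"].values)
    for cohort, tab in cohort_r2.items():
        tab = tab.set_index("id")
        geno = tab["genotyped"].astype(bool) if "genotyped" in tab.columns else pd.Series(False, index=tab.index)
        r2 = tab["r2"] if "r2" in tab.columns else pd.Series(np.nan, index=tab.index)
        ok = geno | (r2 > threshold)
        aligned = ok.reindex(keep.index)
        n_absent = int(aligned.isna().sum())
        if n_absent:
            logger.warning("imputation filter: %d variant(s) absent from cohort %s", n_absent, cohort)
        keep &= aligned.eq(True)  # absent (NaN) counts as failing
    out = ss.table.loc[keep.values].reset_index(drop=True)
    logger.info("imputation filter: retained %d / %d variants", len(out), len(ss.table))
    return SummaryStats(trait=ss.trait, table=out)


def _panel_lookup(panel_variants: Iterable[VariantRecord]):
    by_key, by_id = {}, {}
    for v in panel_variants:
        by_key[v.key] = v
        by_id[v.id] = v
    return by_key, by_id


def harmonize_alleles(
    ss: SummaryStats, panel_variants: Sequence[VariantRecord]
) -> tuple[SummaryStats, HarmonizationReport]:
    """Reconcile effect-allele coding between summary statistics and a panel.

    Variants are matched by (chrom, pos, allele set) with id as fallback.
    A variant whose effect/other alleles are swapped relative to the panel
    gets its beta sign flipped and alleles relabeled.  Strand-ambiguous
    palindromic variants (A/T, C/G) and unmatched variants are dropped.
    Applying harmonization twice equals applying it once.
    """
    by_key, by_id = _panel_lookup(panel_variants)
    rep = HarmonizationReport(n_input=len(ss.table))
    rows = []
    for row in ss.table.itertuples(index=False):
        alleles = frozenset((row.effect_allele, row.other_allele))
        if alleles in _PALINDROMIC:
            rep.n_palindromic_dropped += 1
            continue
        pv = by_key.get((str(row.chrom), int(row.pos), alleles)) or by_id.get(row.id)
        if pv is None:
            rep.n_unmatched_dropped += 1
            continue
        if row.effect_allele == pv.effect_allele and row.other_allele == pv.other_allele:
            rows.append(row._asdict())
        elif row.effect_allele == pv.other_allele and row.other_allele == pv.effect_allele:
            d = row._asdict()
            d["effect_allele"], d["other_allele"] = pv.effect_allele, pv.other_allele
            d["beta"] = -d["beta"]
            rows.append(d)
            rep.n_flipped += 1
        else:
            rep.n_mismatched_dropped += 1
    out = pd.DataFrame(rows, columns=ss.table.columns)
    rep.n_kept = len(out)
    logger.info(
        "harmonization: kept %d/%d (flipped %d, palindromic %d, unmatched %d, mismatched %d)",
        rep.n_kept, rep.n_input, rep.n_flipped, rep.n_palindromic_dropped,
        rep.n_unmatched_dropped, rep.n_mismatched_dropped,
    )
    return SummaryStats(trait=ss.trait, table=out.reset_index(drop=True)), rep


def write_weights(w: PRSWeights, path) -> None:
    """Write weights as TSV with a ``#`` key=value header (lossless round trip)."""
    if len(w.table) == 0:
        raise ValueError("refusing to write empty weights")
    with open(path, "w") as fh:
        fh.write(f"#format_version={WEIGHTS_FORMAT_VERSION}\n")
        fh.write(f"#trait={w.trait}\n")
        fh.write(f"#s={w.s!r}\n")
        fh.write(f"#lambda={w.lam!r}\n")
        fh.write("id\tchrom\tpos\teffect_allele\tweight\n")
        for row in w.table.itertuples(index=False):
            fh.write(f"{row.id}\t{row.chrom}\t{row.pos}\t{row.effect_allele}\t{row.weight!r}\n")


def read_weights(path) -> PRSWeights:
    """Read a weights file written by :func:`write_weights`."""
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            header[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        tab = pd.read_csv(fh, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    if header.get("format_version") != WEIGHTS_FORMAT_VERSION:
        raise SumstatsFormatError(
            f"{path}: unsupported weights format version {header.get('format_version')!r}"
        )
    for k in ("trait", "s", "lambda"):
        if k not in header:
            raise SumstatsFormatError(f"{path}: missing header key {k}")
    return PRSWeights(
        trait=header["trait"], s=float(header["s"]), lam=float(header["lambda"]), table=tab
    )
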