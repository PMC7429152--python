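"""Block-diagonal LD correlation matrices from a reference panel.

The penalized summary-statistic regression needs the SNP-by-SNP correlation
structure of the population the GWAS was run in.  A reference panel (here a
simulated one; in practice genotypes from the training population) supplies
it.  Correlations are taken as zero across blocks, so each block's matrix is
estimated and stored independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["LDBlock", "LDBlocks", "compute_ld_blocks"]

#: diagonal ridge guaranteeing positive semidefiniteness under finite panels
RIDGE = 1e-8


@dataclass
class LDBlock:
    variant_ids: list
    R: np.ndarray  # symmetric, unit diagonal

    def __post_init__(self):
        k = len(self.variant_ids)
        if self.R.shape != (k, k):
            raise ValueError("R shape inconsistent with variant list")


@dataclass
class LDBlocks:
    blocks: list  # list[LDBlock]
    n_ref: int

    @property
    def variant_ids(self) -> list:
        return [v for b in self.blocks for v in b.variant_ids]

    @property
    def m(self) -> int:
        return sum(len(b.variant_ids) for b in self.blocks)

    def block_slices(self):
        """Yield (block, slice into the concatenated variant order)."""
        start = 0
        for b in self.blocks:
            k = len(b.variant_ids)
            yield b, slice(start, start + k)
            start += k


def _resolve_assignment(m: int, block_assignment) -> list:
    """Accept a window size or explicit index lists; return index lists."""
    if isinstance(block_assignment, int):
        if block_assignment < 1:
            raise ValueError("window size must be >= 1")
        return [list(range(i, min(i + block_assignment, m))) for i in range(0, m, block_assignment)]
    idx = [list(b) for b in block_assignment]
    flat = sorted(i for b in idx for i in b)
    if flat != list(range(m)):
        raise ValueError("block assignment must partition the variants exactly once")
    return idx


def compute_ld_blocks(G_ref: GenotypeMatrix, block_assignment=100) -> LDBlocks:
    """Estimate within-block Pearson correlations of reference dosages.

    ``block_assignment`` is either a fixed window size (variants per block) or
    an explicit partition as a list of column-index lists.  Missing dosages
    are mean-imputed before standardization; zero-variance variants are
    excluded from their block (logged).  A small diagonal ridge keeps each
    block positive semidefinite while preserving the unit diagonal.
    """
    if G_ref.n < 2:
        raise ValueError("reference panel needs at least 2 individuals")
    X = G_ref.dosages.astype(float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = X.std(axis=0)

    blocks = []
    for cols in _resolve_assignment(G_ref.m, block_assignment):
        keep = [j for j in cols if sd[j] > 0]
        dropped = len(cols) - len(keep)
        if dropped:
            logger.warning("compute_ld_blocks: excluded %d zero-variance variant(s)", dropped)
        if not keep:
            continue
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        R = (Z.T @ Z) / G_ref.n
        R = (R + R.T) / 2
        k = len(keep)
        R = (R + RIDGE * np.eye(k)) / (1 + RIDGE)  # PSD-preserving, diag stays 1
        np.fill_diagonal(R, 1.0)
        blocks.append(LDBlock(variant_ids=[G_ref.variants[j].id for j in keep], R=R))
    return LDBlocks(blocks=blocks, n_ref=G_ref.n)
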