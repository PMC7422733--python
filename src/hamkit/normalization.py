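"""Expression transforms applied before scoring.

Covers nRPKM (size-factor-normalized reads per kilobase exonic gene model per
million total reads), log2(x+1) stabilization, median-of-ratios size factors,
per-cell total-transcript normalization, per-gene Z-scoring, and IQR-based
variable-gene selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import CellMatrix, ExpressionMatrix


@dataclass
class SizeFactorSet:
    """Per-sample positive scale factors (median-of-ratios)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


def size_factors_median_of_ratios(counts: ExpressionMatrix) -> SizeFactorSet:
    """Median-of-ratios size factors.

    The reference profile is the per-gene geometric mean across samples,
    restricted to genes positive in every sample; each sample's factor is the
    median over those genes of count/reference.  Identical columns yield all
    factors 1.
    """
    mat = counts.values.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene is positive in every sample; cannot form reference")
    sub = mat[all_pos]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return SizeFactorSet(pd.Series(factors, index=counts.sample_ids))


def compute_nrpkm(
    counts: ExpressionMatrix,
    exonic_length_bp: Mapping[str, float],
    use_size_factors: bool = True,
) -> ExpressionMatrix:
    """nRPKM: (count / size factor) per kilobase exonic model per million total reads.

    Genes without a length are dropped with a warning.  With
    ``use_size_factors=False`` (or a single sample) the size factor is 1 and
    the statistic reduces to plain RPKM on raw library size.
    """
    if counts.layer != "counts":
        raise ValueError("nRPKM is computed from the counts layer")
    have = [g for g in counts.gene_ids if g in exonic_length_bp]
    missing = set(counts.gene_ids) - set(have)
    if missing:
        warnings.warn(f"{len(missing)} gene(s) without exonic length dropped from nRPKM")
    lengths = np.array([exonic_length_bp[g] for g in have], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    mat = counts.values.loc[have].to_numpy(dtype=float)
    totals = counts.values.to_numpy(dtype=float).sum(axis=0)  # raw library size
    if use_size_factors and counts.shape[1] >= 2:
        sf = size_factors_median_of_ratios(counts).factors.to_numpy()
    else:
        sf = np.ones(counts.shape[1])
    vals = (mat / sf) / (lengths[:, None] / 1e3) / (totals / 1e6)
    out = pd.DataFrame(vals, index=have, columns=counts.sample_ids)
    return ExpressionMatrix(values=out, layer="nrpkm")


def log_stabilize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1)."""
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log stabilization requires nonnegative values")
    return ExpressionMatrix(values=np.log2(m.values + 1.0), layer="log2stab")


def total_transcript_normalize(cells: CellMatrix, target_total: float | None = None) -> sp.csr_matrix:
    """Scale each cell's counts so its column sums to ``target_total``.

    Defaults to the median cell depth.  Within-cell gene proportions are
    preserved exactly.  Returns a real-valued sparse matrix of the same shape.
    """
    totals = cells.total_umis().astype(float)
    if (totals <= 0).any():
        bad = [cells.cell_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"zero-count cells (should have been QC-filtered): {bad}")
    if target_total is None:
        target_total = float(np.median(totals))
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    scale = target_total / totals
    return sp.csr_matrix(cells.counts.multiply(scale[None, :]))


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Z scores across samples (sample SD, n-1 denominator).

    Zero-variance rows become all zeros with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("Z-scoring requires at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to all-zero Z scores")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd == 0, 0.0, (arr - mean) / np.where(sd == 0, 1.0, sd))
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=m.gene_ids, columns=m.sample_ids), layer="centered"
    )


def top_variable_genes_iqr(m: ExpressionMatrix, n: int) -> list[str]:
    """The ``n`` genes with the largest interquartile range, ties broken lexicographically."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > m.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {m.shape[0]}")
    arr = m.values.to_numpy(dtype=float)
    iqr = np.percentile(arr, 75, axis=1) - np.percentile(arr, 25, axis=1)
    order = sorted(range(len(iqr)), key=lambda i: (-iqr[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:n]]
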