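"""Per-gene linear-model differential expression with Cook's-distance filtering.

Each gene is fit by ordinary least squares on log2-stabilized expression
against a shared design matrix (diagnosis plus optional covariates such as
age, sex, PMI, ApoE4 status).  Because the design is common to all genes, the
hat matrix is computed once and the per-gene coefficient, standard error,
t statistic, and per-sample Cook's distances are fully vectorized.

Genes whose maximum Cook's distance exceeds the upper-0.99 quantile of
F(p, m - p) — the alpha = 0.01 critical value, with p model parameters and m
samples — are flagged as outlier-driven and excluded from DE gene lists.
P values are Benjamini-Hochberg adjusted within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionMatrix, SampleTable


@dataclass
class DEFit:
    """Per-gene OLS results plus influence diagnostics.

    ``table`` has one row per gene with columns log2fc, se, t, p, padj,
    cooks_max, cooks_pass.  ``cooks`` holds the full genes x samples Cook's
    distance matrix so the filter can be re-derived or audited.
    """

    table: pd.DataFrame
    coefficient: str
    n_samples: int
    n_params: int
    cooks: pd.DataFrame = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)


@dataclass
class FourWayResult:
    """Gene-by-gene DE concordance between two datasets."""

    table: pd.DataFrame  # log2fc_a, log2fc_b, sig_a, sig_b, sig_class, quadrant
    class_counts: pd.Series
    quadrant_counts: pd.Series
    sign_concordance: float


def build_design(samples: SampleTable, columns: list[str]) -> pd.DataFrame:
    """Numeric design matrix (with intercept) from sample-table columns.

    ``diagnosis`` becomes an AD indicator; ``sex`` a male indicator; boolean
    columns become 0/1; numeric columns pass through.
    """
    cols = {"intercept": np.ones(len(samples.sample_ids))}
    for c in columns:
        s = samples[c]
        if c == "diagnosis":
            cols["diagnosis"] = (s == "AD").astype(float).to_numpy()
        elif c == "sex":
            cols["sex"] = (s.astype(str).str.upper().isin(["M", "MALE"])).astype(float).to_numpy()
        elif s.dtype == bool:
            cols[c] = s.astype(float).to_numpy()
        else:
            cols[c] = pd.to_numeric(s).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=samples.sample_ids)


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify a culprit column whose removal restores full column rank
        for j, name in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"design matrix is rank deficient; column {name!r} is collinear")
        raise ValueError("design matrix is rank deficient")


def fit_gene_linear_models(
    logm: ExpressionMatrix,
    design: pd.DataFrame,
    coefficient: str,
) -> DEFit:
    """OLS per gene of log-stabilized expression on the design; vectorized over genes."""
    if coefficient not in design.columns:
        raise ValueError(f"coefficient {coefficient!r} not in design")
    design = design.loc[logm.sample_ids]
    X = design.to_numpy(dtype=float)
    m, p = X.shape
    if m < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p} parameters, got {m}")
    _check_full_rank(design)
    Y = logm.values.to_numpy(dtype=float).T  # samples x genes

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # p x genes
    H = X @ XtX_inv @ X.T
    h = np.diag(H)
    resid = Y - X @ beta  # samples x genes
    df = m - p
    rss = (resid**2).sum(axis=0)
    # a numerically perfect fit leaves only rounding noise in the residuals;
    # treat it as zero residual (se 0, p -> 0, no influence) rather than
    # dividing rounding error by rounding error
    perfect = rss <= 1e-20 + 1e-14 * (Y**2).sum(axis=0)
    s2 = np.where(perfect, 0.0, rss / df)
    j = list(design.columns).index(coefficient)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * XtX_inv[j, j])
        t = np.where(se > 0, beta[j] / np.where(se > 0, se, 1.0), np.inf * np.sign(beta[j]))
        pvals = 2 * stats.t.sf(np.abs(t), df)
        pvals = np.where(np.isfinite(t), pvals, 0.0)
        # Cook's D_ij = r_ij^2 h_i / (p s2_j (1 - h_i)^2), genes x samples
        denom = p * s2[None, :] * (1 - h[:, None]) ** 2
        cooks = np.where(denom > 0, resid**2 * h[:, None] / np.where(denom > 0, denom, 1.0), 0.0).T

    table = pd.DataFrame(
        {
            "log2fc": beta[j],
            "se": se,
            "t": t,
            "p": pvals,
            "padj": np.nan,
            "cooks_max": cooks.max(axis=1),
            "cooks_pass": True,
        },
        index=logm.gene_ids,
    )
    cooks_df = pd.DataFrame(cooks, index=logm.gene_ids, columns=logm.sample_ids)
    return DEFit(table=table, coefficient=coefficient, n_samples=m, n_params=p,
                 cooks=cooks_df, design=design)


def cooks_critical_value(n_params: int, n_samples: int, alpha: float = 0.01) -> float:
    """Upper-alpha critical value of F(p, m - p): the 1 - alpha quantile."""
    if n_samples <= n_params:
        raise ValueError("need more samples than parameters")
    return float(stats.f.ppf(1 - alpha, n_params, n_samples - n_params))


def cooks_filter(fit: DEFit, alpha: float = 0.01) -> DEFit:
    """Flag genes whose maximum Cook's distance exceeds the F critical value."""
    crit = cooks_critical_value(fit.n_params, fit.n_samples, alpha)
    fit.table["cooks_pass"] = fit.table["cooks_max"] <= crit
    return fit


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def adjust_fit(fit: DEFit) -> DEFit:
    fit.table["padj"] = bh_adjust(fit.table["p"])
    return fit


def call_de(fit: DEFit, adj_p_max: float = 0.05) -> tuple[list[str], list[str]]:
    """Up/down gene lists at the adjusted-p threshold among Cook's-passing genes."""
    tab = fit.table
    if tab["padj"].isna().any():
        fit = adjust_fit(fit)
        tab = fit.table
    sig = tab[(tab["padj"] <= adj_p_max) & tab["cooks_pass"]]
    up = sig.index[sig["log2fc"] > 0].tolist()
    down = sig.index[sig["log2fc"] < 0].tolist()
    return up, down


def fourway_concordance(
    de_a: DEFit, de_b: DEFit, sig_a: float = 0.05, sig_b: float = 0.05
) -> FourWayResult:
    """Cross-dataset fold-change comparison with per-gene significance classes."""
    shared = de_a.table.index.intersection(de_b.table.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two DE results")
    a = de_a.table.loc[shared]
    b = de_b.table.loc[shared]
    is_sig_a = (a["padj"] <= sig_a) & a["cooks_pass"]
    is_sig_b = (b["padj"] <= sig_b) & b["cooks_pass"]
    sig_class = np.select(
        [is_sig_a & is_sig_b, is_sig_a & ~is_sig_b, ~is_sig_a & is_sig_b],
        ["both", "A only", "B only"],
        default="neither",
    )
    quadrant = np.where(
        a["log2fc"] >= 0,
        np.where(b["log2fc"] >= 0, "up/up", "up/down"),
        np.where(b["log2fc"] >= 0, "down/up", "down/down"),
    )
    table = pd.DataFrame(
        {
            "log2fc_a": a["log2fc"], "log2fc_b": b["log2fc"],
            "sig_a": is_sig_a, "sig_b": is_sig_b,
            "sig_class": sig_class, "quadrant": quadrant,
        },
        index=shared,
    )
    either = table[table["sig_a"] | table["sig_b"]]
    if len(either):
        concord = float((np.sign(either["log2fc_a"]) == np.sign(either["log2fc_b"])).mean())
    else:
        concord = float("nan")
    return FourWayResult(
        table=table,
        class_counts=table["sig_class"].value_counts(),
        quadrant_counts=table["quadrant"].value_counts(),
        sign_concordance=concord,
    )
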