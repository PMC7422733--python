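"""Cohort-characteristics statistics: exact 2x2 tests, two-sample t tests,
and median/IQR summaries, assembled into a demographics table.

Binary variables (sex, ApoE4 carrier status) are tested with Fisher's exact
test; continuous variables (age, PMI, MMSE) with a two-sample t test and
summarized as median (Q1-Q3).  The two-sided Fisher p is the sum of
hypergeometric point probabilities over all tables with the observed margins
that are no more probable than the observed table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ContingencyTable2x2, SampleTable


def fisher_exact_two_sided(table: ContingencyTable2x2, convention: str = "sum") -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    ``sum`` (default) sums point probabilities <= that of the observed table;
    ``doubling`` doubles the smaller one-sided tail (capped at 1).
    A table with a zero margin carries no information: p = 1 with a warning.
    """
    t = table.counts
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("2x2 table has a zero margin; p = 1 by convention")
        return 1.0
    if convention == "sum":
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    if convention == "doubling":
        less = stats.fisher_exact(t, alternative="less")[1]
        greater = stats.fisher_exact(t, alternative="greater")[1]
        return float(min(1.0, 2 * min(less, greater)))
    raise ValueError(f"unknown convention {convention!r}")


def student_t_two_sample(x, y, variant: str = "student") -> float:
    """Two-sided two-sample t-test p (pooled variance, or Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 1.0
    p = float(stats.ttest_ind(x, y, equal_var=(variant == "student")).pvalue)
    return 1.0 if np.isnan(p) else p


def median_iqr(x) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return (float(np.median(x)),
            float(np.percentile(x, 25)),
            float(np.percentile(x, 75)))


# variable name -> kind; binary variables get Fisher, continuous get t + median/IQR
DEFAULT_VARIABLES: dict[str, str] = {
    "sex": "binary",
    "apoe4": "binary",
    "age": "continuous",
    "pmi": "continuous",
    "mmse": "continuous",
}


def build_cohort_table(
    meta: SampleTable,
    group_col: str = "diagnosis",
    variables: dict[str, str] | None = None,
    variant: str = "student",
) -> pd.DataFrame:
    """Demographics table: per-variable group summaries and the matching test p."""
    variables = variables or {
        k: v for k, v in DEFAULT_VARIABLES.items() if k in meta.data.columns
    }
    groups = meta[group_col]
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group column {group_col!r} must be binary, got {levels}")
    g0, g1 = levels
    rows = []
    for var, kind in variables.items():
        s = meta[var]
        x = s[groups == g0].dropna()
        y = s[groups == g1].dropna()
        if kind == "binary":
            if var == "sex":
                pos = lambda v: v.astype(str).str.upper().isin(["M", "MALE"])
            else:
                pos = lambda v: v.astype(bool)
            a, b = int(pos(x).sum()), int(pos(y).sum())
            tab = ContingencyTable2x2(np.array([[a, len(x) - a], [b, len(y) - b]]))
            p = fisher_exact_two_sided(tab)
            rows.append({
                "variable": var, "test": "fisher_exact",
                f"{g0}": f"{a} ({100 * a / len(x):.0f}%)",
                f"{g1}": f"{b} ({100 * b / len(y):.0f}%)",
                "p": p,
            })
        elif kind == "continuous":
            x = pd.to_numeric(x).to_numpy()
            y = pd.to_numeric(y).to_numpy()
            m0, q10, q30 = median_iqr(x)
            m1, q11, q31 = median_iqr(y)
            p = student_t_two_sample(x, y, variant=variant)
            rows.append({
                "variable": var, "test": f"t_{variant}",
                f"{g0}": f"{m0:g} ({q10:g}-{q30:g})",
                f"{g1}": f"{m1:g} ({q11:g}-{q31:g})",
                "p": p,
            })
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows).set_index("variable")
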