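"""Fluidigm-style qPCR Ct processing.

Pipeline order (pinned by tests): per-assay detection-ceiling imputation ->
duplicate reconciliation -> global-median delta-Ct -> per-assay group DE.

* Ceiling imputation: per assay, the maximum Ct among quality > 0 records
  (maxCt) is computed on the raw replicate records; every record with
  Ct > maxCt (including the 999 undetected sentinel) is set to maxCt + 0.5.
* Duplicates whose two Cts differ by more than 2.82 cycles (a replicate
  standard deviation of 2.82 / sqrt(2) ~ 2) are discarded as irreproducible;
  otherwise their mean is kept.
* delta-Ct(sample, assay) = Ct - median Ct over that sample's assays, so a
  lower delta-Ct means higher expression.  Group effects are reported on the
  expression scale (-delta-Ct) so that a positive effect means higher
  expression in AD, comparable in sign to RNA-seq log2 fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, SampleTable
from . import diffexp

UNDETECTED_CT = 999.0


@dataclass
class QpcrPlate:
    """Long-format Ct records: sample_id, assay_id, replicate, ct, quality."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "assay_id", "replicate", "ct", "quality"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"qPCR plate missing columns: {sorted(missing)}")
        if (self.records["ct"] <= 0).any():
            raise ValueError("Ct values must be positive (999 marks undetected)")
        if (self.records["quality"] < 0).any():
            raise ValueError("quality must be >= 0")


@dataclass
class DeltaCtTable:
    """Sample x assay delta-Ct values plus the per-sample global median used."""

    values: pd.DataFrame  # rows samples, columns assays
    global_median: pd.Series


def read_qpcr(path) -> QpcrPlate:
    return QpcrPlate(pd.read_csv(path))


def impute_ceiling(plate: QpcrPlate) -> QpcrPlate:
    """Per assay, set every Ct above the quality>0 maximum (maxCt) to maxCt + 0.5."""
    rec = plate.records.copy()
    out = []
    for assay, grp in rec.groupby("assay_id", sort=False):
        good = grp.loc[grp["quality"] > 0, "ct"]
        if good.empty:
            warnings.warn(f"assay {assay!r} has no quality>0 record; dropped")
            continue
        max_ct = good.max()
        grp = grp.copy()
        grp.loc[grp["ct"] > max_ct, "ct"] = max_ct + 0.5
        out.append(grp)
    return QpcrPlate(pd.concat(out, ignore_index=True))


def collapse_duplicates(
    plate: QpcrPlate, max_abs_diff: float = 2.82
) -> tuple[QpcrPlate, pd.DataFrame]:
    """Average duplicate Cts; discard pairs differing by more than ``max_abs_diff``.

    Returns the collapsed plate (one record per sample x assay) and a table
    of the discarded pairs with both Cts.
    """
    rec = plate.records
    collapsed, discarded = [], []
    for (sample, assay), grp in rec.groupby(["sample_id", "assay_id"], sort=False):
        cts = grp["ct"].to_numpy(dtype=float)
        if len(cts) > 2:
            raise ValueError(f"more than 2 replicates for {sample}/{assay}")
        # tolerance guards the threshold itself against float representation
        # (22.82 - 20.0 is not exactly 2.82 in binary)
        if len(cts) == 2 and abs(cts[0] - cts[1]) > max_abs_diff + 1e-9:
            discarded.append({"sample_id": sample, "assay_id": assay,
                              "ct1": cts[0], "ct2": cts[1]})
            continue
        collapsed.append({"sample_id": sample, "assay_id": assay, "replicate": 1,
                          "ct": float(cts.mean()), "quality": float(grp["quality"].min())})
    cols = ["sample_id", "assay_id", "replicate", "ct", "quality"]
    return (QpcrPlate(pd.DataFrame(collapsed, columns=cols)),
            pd.DataFrame(discarded, columns=["sample_id", "assay_id", "ct1", "ct2"]))


def delta_ct(plate: QpcrPlate) -> DeltaCtTable:
    """Global-median delta-Ct: subtract each sample's median Ct across assays."""
    wide = plate.records.pivot_table(index="sample_id", columns="assay_id", values="ct")
    few = wide.notna().sum(axis=1) < 3
    if few.any():
        warnings.warn(
            f"{int(few.sum())} sample(s) with < 3 assays; global median unstable"
        )
    med = wide.median(axis=1)
    return DeltaCtTable(values=wide.sub(med, axis=0), global_median=med)


def qpcr_group_de(
    dct: DeltaCtTable, groups: pd.Series | SampleTable, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-assay linear-model DE on the expression scale (-delta-Ct); BH across assays.

    A positive effect means higher expression in AD.  Delta-Ct tables from a
    collapsed plate may have gaps where duplicate pairs were discarded; each
    assay is fit on the samples for which it has a value.
    """
    if isinstance(groups, SampleTable):
        groups = groups["diagnosis"]
    expr = -dct.values.T  # assays x samples, expression scale
    results = {}
    for assay, row in expr.iterrows():
        avail = row.dropna()
        g = groups.loc[avail.index]
        if (g == "AD").sum() < 2 or (g != "AD").sum() < 2:
            raise ValueError(f"assay {assay!r}: need >= 2 samples per group")
        sub = ExpressionMatrix(
            values=pd.DataFrame([avail.to_numpy(dtype=float)], index=[str(assay)],
                                columns=list(avail.index)),
            layer="log2stab",
        )
        design = pd.DataFrame(
            {"intercept": 1.0, "diagnosis": (g == "AD").astype(float)}, index=avail.index
        )
        if covariates is not None:
            design = design.join(covariates.loc[avail.index])
        fit = diffexp.fit_gene_linear_models(sub, design, "diagnosis")
        r = fit.table.iloc[0]
        results[assay] = {"effect": r["log2fc"], "p": r["p"]}
    out = pd.DataFrame(results).T
    out["padj"] = diffexp.bh_adjust(out["p"])
    return out
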