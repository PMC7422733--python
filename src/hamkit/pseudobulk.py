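"""Per-study single-cell QC filters and pseudobulk aggregation.

Each external single-cell/nucleus study used its own QC rule, captured here
as presets with the exact boundary semantics of the source descriptions:

* ``masuda``      — keep cells with >= 800 total transcripts and <= 30% mito
                    (discard "less than 800" or "greater than 30%")
* ``jakel``       — keep nuclei with "at least" 400 total UMIs
* ``hasselmann``  — keep cells with log10(total UMIs) >= 3.25 and "at most"
                    5% mitochondrial transcripts

A pseudobulk profile for a (sample, cell type) pair is the per-gene sum of
UMIs over all its cells; pairs with fewer than ``min_cells`` (default 10)
cells are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import CellMatrix, ExpressionMatrix
from .normalization import size_factors_median_of_ratios


@dataclass
class QcRule:
    """Cell-level QC thresholds; a cell is kept iff it satisfies every set criterion."""

    min_total_umi: int | None = None
    min_log10_umi: float | None = None
    max_mito_fraction: float | None = None
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if self.min_total_umi is None and self.min_log10_umi is None and self.max_mito_fraction is None:
            raise ValueError("QC rule must set at least one criterion")
        if self.max_mito_fraction is not None and not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


QC_PRESETS: dict[str, QcRule] = {
    "masuda": QcRule(min_total_umi=800, max_mito_fraction=0.30, preset_name="masuda"),
    "jakel": QcRule(min_total_umi=400, preset_name="jakel"),
    "hasselmann": QcRule(min_log10_umi=3.25, max_mito_fraction=0.05, preset_name="hasselmann"),
}


@dataclass
class PseudobulkMatrix:
    """Genes x (sample, cell type) summed-UMI matrix with per-column cell counts."""

    values: pd.DataFrame  # columns are "sample|cell_type" labels
    columns: list[tuple[str, str]]
    cells_per_column: pd.Series
    min_cells: int


def qc_filter_cells(cells: CellMatrix, rule: QcRule) -> tuple[CellMatrix, dict]:
    """Apply a QC rule; returns the filtered matrix and a per-criterion report."""
    totals = cells.total_umis()
    keep = np.ones(cells.n_cells, dtype=bool)
    report: dict = {"preset": rule.preset_name, "n_input": cells.n_cells}
    if rule.min_total_umi is not None:
        ok = totals >= rule.min_total_umi
        report["fail_min_total_umi"] = int((~ok).sum())
        keep &= ok
    if rule.min_log10_umi is not None:
        with np.errstate(divide="ignore"):
            ok = np.log10(np.maximum(totals, 1e-300)) >= rule.min_log10_umi
        report["fail_min_log10_umi"] = int((~ok).sum())
        keep &= ok
    if rule.max_mito_fraction is not None:
        if not cells.mito_genes:
            raise ValueError("mito criterion set but no mitochondrial genes defined")
        ok = cells.mito_fraction() <= rule.max_mito_fraction
        report["fail_max_mito_fraction"] = int((~ok).sum())
        keep &= ok
    report["n_kept"] = int(keep.sum())
    return cells.subset_cells(keep), report


def aggregate_pseudobulk(cells: CellMatrix, min_cells: int = 10) -> PseudobulkMatrix:
    """Sum UMIs per gene over each (sample, cell type) group with >= min_cells cells."""
    if cells.n_cells == 0:
        warnings.warn("no cells to aggregate; empty pseudobulk matrix")
        return PseudobulkMatrix(
            values=pd.DataFrame(index=cells.gene_ids),
            columns=[], cells_per_column=pd.Series(dtype=int), min_cells=min_cells,
        )
    pairs = list(zip(cells.cell_sample.values, cells.cell_type.values))
    groups: dict[tuple[str, str], list[int]] = {}
    for j, key in enumerate(pairs):
        groups.setdefault(key, []).append(j)
    kept = sorted(k for k, idx in groups.items() if len(idx) >= min_cells)
    cols, counts = {}, {}
    for key in kept:
        idx = groups[key]
        label = f"{key[0]}|{key[1]}"
        cols[label] = np.asarray(cells.counts[:, idx].sum(axis=1)).ravel()
        counts[label] = len(idx)
    values = pd.DataFrame(cols, index=cells.gene_ids)
    return PseudobulkMatrix(
        values=values,
        columns=kept,
        cells_per_column=pd.Series(counts, dtype=int),
        min_cells=min_cells,
    )


def pseudobulk_normalize(pb: PseudobulkMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization of the pseudobulk count matrix."""
    if pb.values.shape[1] < 2:
        raise ValueError("pseudobulk normalization needs >= 2 columns")
    counts = ExpressionMatrix(values=pb.values.astype(float), layer="counts")
    sf = size_factors_median_of_ratios(counts).factors
    normed = pb.values.astype(float).div(sf, axis=1)
    return ExpressionMatrix(values=normed, layer="normalizedCount")
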