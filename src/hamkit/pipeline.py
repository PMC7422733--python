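"""Orchestration of the three analysis tracks.

* ``sorted_cells`` — log-stabilize, center on controls, score gene sets,
  compare AD vs control.
* ``whole_tissue_balanced`` — score the myeloid marker set, balance the
  cohort within myeloid-score bins, drop neuronal-enriched genes from target
  sets, restrict to shared genes, score on the balanced subset, compare.
* ``pseudobulk`` — QC-filter cells, aggregate per (sample, cell type),
  median-of-ratios normalize, log-stabilize, center on the dataset's
  controls, score with APOE removed, compare.

Centering is always within one dataset, never across datasets; cross-dataset
comparisons only ever use gene sets after shared-gene restriction.  Every run
writes a manifest (seeds, set sizes, dropped-gene counts) for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import geneset_scoring as gs
from . import normalization, pseudobulk
from .core_data import CellMatrix, ExpressionMatrix, GeneSet, SampleTable

logger = logging.getLogger(__name__)

TRACKS = ("sorted_cells", "whole_tissue_balanced", "pseudobulk")


@dataclass
class RunConfig:
    """Inputs and parameters for one analysis track on one dataset."""

    dataset_label: str
    gene_sets: list[GeneSet]
    control_label: str = "control"
    ad_label: str = "AD"
    myeloid_set: GeneSet | None = None
    neuronal_exclusion: list[str] = field(default_factory=list)
    apoe_exclusion: list[str] = field(default_factory=lambda: ["APOE"])
    n_bins: int = 20
    seed: int | None = None
    qc_preset: str = "custom"
    min_cells: int = 10
    target_cell_type: str = "microglia"
    t_variant: str = "student"
    output_dir: Path | None = None


@dataclass
class TrackResult:
    """Per-set scores and group comparisons plus the run manifest."""

    scores: dict[str, gs.ScoreTable]
    comparisons: pd.DataFrame
    manifest: dict
    balance_plan: gs.BalancePlan | None = None


def _score_and_compare(
    centered: ExpressionMatrix,
    sets: list[GeneSet],
    diagnosis: pd.Series,
    config: RunConfig,
    sample_ids: list[str] | None = None,
) -> tuple[dict[str, gs.ScoreTable], pd.DataFrame]:
    scores: dict[str, gs.ScoreTable] = {}
    rows = []
    for gset in sets:
        if len(gset) == 0:
            logger.warning("gene set %s empty; skipped", gset.name)
            continue
        table = gs.de_score(centered, gset, dataset_label=config.dataset_label)
        if sample_ids is not None:
            table = table.subset(sample_ids)
        scores[gset.name] = table
        dx = diagnosis.loc[table.scores.index]
        n_ctrl = int((dx == config.control_label).sum())
        n_ad = int((dx == config.ad_label).sum())
        if n_ctrl >= 2 and n_ad >= 2:
            cmp = gs.compare_groups(
                table, dx, group_a=config.control_label, group_b=config.ad_label,
                variant=config.t_variant,
            )
            delta, p = cmp.delta, cmp.p_value
        else:
            # a single control sample still supports centering and a delta,
            # but no t test
            ad_mean = table.scores[dx == config.ad_label].mean()
            ctrl_mean = table.scores[dx == config.control_label].mean()
            delta, p = float(ad_mean - ctrl_mean), float("nan")
        rows.append(
            {"gene_set": gset.name, "delta": delta, "p": p,
             "n_control": n_ctrl, "n_ad": n_ad, "n_genes_used": table.n_genes_used}
        )
    return scores, pd.DataFrame(rows).set_index("gene_set")


def run_sorted_cells(
    expr: ExpressionMatrix, meta: SampleTable, config: RunConfig
) -> TrackResult:
    """Score sorted-cell profiles: log-stabilize, control-center, score, compare."""
    logm = normalization.log_stabilize(expr) if expr.layer != "log2stab" else expr
    controls = [s for s in logm.sample_ids if meta["diagnosis"].get(s) == config.control_label]
    centered = gs.control_center(logm, controls)
    scores, comparisons = _score_and_compare(centered, config.gene_sets, meta["diagnosis"], config)
    manifest = {
        "track": "sorted_cells", "dataset": config.dataset_label,
        "n_samples": len(logm.sample_ids), "n_controls": len(controls),
        "set_sizes": {s.name: len(s) for s in config.gene_sets},
    }
    return TrackResult(scores=scores, comparisons=comparisons, manifest=manifest)


def run_whole_tissue_balanced(
    expr: ExpressionMatrix, meta: SampleTable, config: RunConfig
) -> TrackResult:
    """Myeloid-balance a whole-tissue cohort, then score neuronal-excluded sets."""
    if config.myeloid_set is None:
        raise ValueError("whole-tissue balancing requires a myeloid marker set")
    if config.seed is None:
        raise ValueError("balancing requires an explicit seed")
    logm = normalization.log_stabilize(expr) if expr.layer != "log2stab" else expr
    controls = [s for s in logm.sample_ids if meta["diagnosis"].get(s) == config.control_label]
    centered = gs.control_center(logm, controls)

    myeloid_scores = gs.gene_set_score(centered, config.myeloid_set, config.dataset_label)
    plan = gs.myeloid_balance(
        myeloid_scores, meta["diagnosis"], n_bins=config.n_bins, seed=config.seed,
        ad_label=config.ad_label,
    )
    sets = [gs.exclude_genes(s, config.neuronal_exclusion) for s in config.gene_sets]
    sets = gs.restrict_to_shared_genes(sets, [logm])
    scores, comparisons = _score_and_compare(
        centered, sets, meta["diagnosis"], config, sample_ids=plan.kept_sample_ids
    )
    manifest = {
        "track": "whole_tissue_balanced", "dataset": config.dataset_label,
        "seed": config.seed, "n_bins": config.n_bins,
        "n_kept": len(plan.kept_sample_ids), "n_discarded": len(plan.discarded_sample_ids),
        "set_sizes": {s.name: len(s) for s in sets},
        "neuronal_excluded": len(config.neuronal_exclusion),
    }
    return TrackResult(scores=scores, comparisons=comparisons, manifest=manifest,
                       balance_plan=plan)


def run_pseudobulk(
    cells: CellMatrix, sample_diagnosis: pd.Series, config: RunConfig
) -> TrackResult:
    """QC, aggregate, normalize, center on controls, score with APOE removed."""
    if config.qc_preset != "custom":
        rule = pseudobulk.QC_PRESETS[config.qc_preset]
        cells, qc_report = pseudobulk.qc_filter_cells(cells, rule)
    else:
        qc_report = {"preset": "none", "n_kept": cells.n_cells}
    pb = pseudobulk.aggregate_pseudobulk(cells, min_cells=config.min_cells)
    target_cols = [
        f"{s}|{c}" for (s, c) in pb.columns if c == config.target_cell_type
    ]
    if len(target_cols) < 2:
        raise ValueError(
            f"fewer than 2 pseudobulk profiles for cell type {config.target_cell_type!r}"
        )
    sub = pseudobulk.PseudobulkMatrix(
        values=pb.values[target_cols],
        columns=[(s, c) for (s, c) in pb.columns if c == config.target_cell_type],
        cells_per_column=pb.cells_per_column.loc[target_cols],
        min_cells=pb.min_cells,
    )
    normed = pseudobulk.pseudobulk_normalize(sub)
    logm = normalization.log_stabilize(normed)
    col_dx = pd.Series(
        {f"{s}|{c}": sample_diagnosis.get(s) for (s, c) in sub.columns}
    )
    controls = [col for col in logm.sample_ids if col_dx[col] == config.control_label]
    if not controls:
        raise ValueError("no control pseudobulk profiles to center on")
    centered = gs.control_center(logm, controls)
    sets = [gs.exclude_genes(s, config.apoe_exclusion) for s in config.gene_sets]
    scores, comparisons = _score_and_compare(centered, sets, col_dx, config)
    manifest = {
        "track": "pseudobulk", "dataset": config.dataset_label,
        "qc": qc_report, "min_cells": config.min_cells,
        "n_pseudobulks": len(target_cols), "n_controls": len(controls),
        "set_sizes": {s.name: len(s) for s in sets},
    }
    return TrackResult(scores=scores, comparisons=comparisons, manifest=manifest)


def run_track(track: str, config: RunConfig, **inputs) -> TrackResult:
    """Dispatch one named track; writes outputs if config.output_dir is set."""
    if track == "sorted_cells":
        result = run_sorted_cells(inputs["expr"], inputs["meta"], config)
    elif track == "whole_tissue_balanced":
        result = run_whole_tissue_balanced(inputs["expr"], inputs["meta"], config)
    elif track == "pseudobulk":
        result = run_pseudobulk(inputs["cells"], inputs["sample_diagnosis"], config)
    else:
        raise ValueError(f"unknown track {track!r}; expected one of {TRACKS}")
    if config.output_dir is not None:
        write_result(result, config.output_dir)
    return result


def write_result(result: TrackResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.comparisons.to_csv(outdir / "comparisons.csv", float_format="%.12g")
    score_df = pd.DataFrame({name: t.scores for name, t in result.scores.items()})
    score_df.index.name = "sample_id"
    score_df.to_csv(outdir / "scores.csv", float_format="%.12g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    if result.balance_plan is not None:
        plan = result.balance_plan
        with open(outdir / "balance_plan.json", "w") as fh:
            json.dump(
                {"n_bins": plan.n_bins, "seed": plan.seed,
                 "bin_edges": [float(e) for e in plan.bin_edges],
                 "kept": plan.kept_sample_ids, "discarded": plan.discarded_sample_ids},
                fh, indent=2,
            )
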