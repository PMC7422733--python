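"""Control-centered gene set scores, signed DE scores, and myeloid balancing.

The gene set score of a sample is the mean, over the genes of a set, of its
log-stabilized expression after subtracting each gene's mean over the
dataset's control samples.  A score of 0.3 therefore reads as "the set is on
average 0.3 log2 units above the control level in this sample".  The DE score
is the signed variant: genes annotated as down-regulated contribute with
weight -1, so coordinated movement of up- and down-genes accumulates in a
single number.

Myeloid balancing removes the confound between diagnosis and myeloid-cell
abundance in whole-tissue cohorts: samples are binned by their myeloid
gene set score and, within each bin, the over-represented diagnosis group is
randomly thinned until the bin's AD fraction matches the cohort-wide target
as closely as discarding allows.  Bins containing a single group carry no
information about the within-abundance effect and are dropped wholly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix, GeneSet, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-sample scores for one gene set on one dataset (log2 scale)."""

    scores: pd.Series
    gene_set_name: str
    n_genes_used: int
    dataset_label: str = ""

    def subset(self, sample_ids) -> "ScoreTable":
        return ScoreTable(
            scores=self.scores.loc[list(sample_ids)],
            gene_set_name=self.gene_set_name,
            n_genes_used=self.n_genes_used,
            dataset_label=self.dataset_label,
        )


@dataclass
class GroupComparison:
    """Difference of group mean scores (log2 scale) with a two-sided t-test p."""

    delta: float
    p_value: float
    group_sizes: tuple[int, int]
    variant: str = "student"


@dataclass
class BalancePlan:
    """Outcome of myeloid balancing: which samples were kept/discarded per bin."""

    n_bins: int
    bin_edges: np.ndarray
    kept_sample_ids: list[str]
    discarded_sample_ids: list[str]
    seed: int
    bin_assignment: pd.Series = field(default=None)


def control_center(logm: ExpressionMatrix, control_ids) -> ExpressionMatrix:
    """Subtract each gene's mean over the control samples from all samples."""
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control set is empty")
    missing = [s for s in control_ids if s not in logm.values.columns]
    if missing:
        raise ValueError(f"control samples not in matrix: {missing}")
    ctrl_mean = logm.values[control_ids].mean(axis=1)
    centered = logm.values.sub(ctrl_mean, axis=0)
    return ExpressionMatrix(values=centered, layer="centered")


def _score(centered: ExpressionMatrix, gene_set: GeneSet, signed: bool, dataset_label: str) -> ScoreTable:
    if centered.layer != "centered":
        raise ValueError("scores are computed on control-centered values")
    present = [g for g in gene_set.members if g in centered.values.index]
    absent = set(gene_set.members) - set(present)
    if not present:
        raise ValueError(f"no member of gene set {gene_set.name!r} present in the matrix")
    if absent:
        logger.info("gene set %s: %d member(s) absent from matrix", gene_set.name, len(absent))
    sub = centered.values.loc[present]
    if signed:
        w = np.array([gene_set.direction[g] for g in present], dtype=float)
        vals = sub.mul(w, axis=0).mean(axis=0)
    else:
        vals = sub.mean(axis=0)
    return ScoreTable(
        scores=vals,
        gene_set_name=gene_set.name,
        n_genes_used=len(present),
        dataset_label=dataset_label,
    )


def gene_set_score(centered: ExpressionMatrix, gene_set: GeneSet, dataset_label: str = "") -> ScoreTable:
    """Unweighted mean of control-centered values over the set's present members."""
    return _score(centered, gene_set, signed=False, dataset_label=dataset_label)


def de_score(centered: ExpressionMatrix, gene_set: GeneSet, dataset_label: str = "") -> ScoreTable:
    """Signed mean: up genes weighted +1, down genes -1."""
    return _score(centered, gene_set, signed=True, dataset_label=dataset_label)


def restrict_to_shared_genes(sets: list[GeneSet], datasets: list[ExpressionMatrix]) -> list[GeneSet]:
    """Intersect each set with the genes present in every dataset compared."""
    if not datasets:
        raise ValueError("need at least one dataset")
    shared = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        shared &= set(ds.gene_ids)
    out = []
    for gs in sets:
        members = [g for g in gs.members if g in shared]
        if not members:
            warnings.warn(f"gene set {gs.name!r} empty after cross-study restriction")
        out.append(GeneSet(name=gs.name, members=members,
                           direction={g: gs.direction[g] for g in members}))
    return out


def exclude_genes(gene_set: GeneSet, exclusion) -> GeneSet:
    """Drop the listed genes (e.g. neuronal-enriched genes, or APOE) from a set."""
    excl = set(exclusion)
    members = [g for g in gene_set.members if g not in excl]
    if not members:
        warnings.warn(f"gene set {gene_set.name!r} empty after exclusion")
    return GeneSet(name=gene_set.name, members=members,
                   direction={g: gene_set.direction[g] for g in members})


def _quantile_bins(scores: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count bins of the pooled scores; ties assigned to the lower bin."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(scores, qs)
    inner = edges[1:-1]
    # side='left': a score equal to an edge lands in the lower bin
    assignment = np.searchsorted(inner, scores, side="left")
    return assignment, edges


def _width_bins(scores: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(scores.min(), scores.max(), n_bins + 1)
    assignment = np.clip(np.searchsorted(edges[1:-1], scores, side="left"), 0, n_bins - 1)
    return assignment, edges


def myeloid_balance(
    scores: ScoreTable,
    diagnosis: pd.Series | SampleTable,
    n_bins: int = 20,
    seed: int = 0,
    ad_label: str = "AD",
    binning: str = "quantile",
) -> BalancePlan:
    """Thin diagnosis groups within myeloid-score bins toward the global AD fraction.

    ``diagnosis`` is a per-sample label series (or a SampleTable with a
    ``diagnosis`` column).  Bins containing a single group are dropped first;
    the target is the AD fraction among the remaining (mixed-bin) samples.
    Within each mixed bin, samples of the over-represented group are then
    discarded uniformly at random (seeded) until the bin's AD fraction is as
    close to the target as any discard-only plan allows.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if isinstance(diagnosis, SampleTable):
        diagnosis = diagnosis["diagnosis"]
    diagnosis = diagnosis.loc[scores.scores.index]
    is_ad = (diagnosis == ad_label).to_numpy()
    if is_ad.all() or (~is_ad).all():
        raise ValueError("both diagnosis groups must be nonempty")
    vals = scores.scores.to_numpy(dtype=float)
    sample_ids = np.array(scores.scores.index)
    if binning == "quantile":
        assignment, edges = _quantile_bins(vals, n_bins)
    elif binning == "width":
        assignment, edges = _width_bins(vals, n_bins)
    else:
        raise ValueError(f"unknown binning {binning!r}")

    rng = np.random.Generator(np.random.Philox(seed))
    kept: list[str] = []
    discarded: list[str] = []
    # single-group bins cannot be mixed toward any target: drop them first,
    # then take the AD fraction of the remaining (mixable) samples as target
    mixed_bins: list[int] = []
    mixable = np.zeros(len(sample_ids), dtype=bool)
    for b in range(n_bins):
        in_bin = assignment == b
        if not in_bin.any():
            continue
        if (in_bin & is_ad).any() and (in_bin & ~is_ad).any():
            mixed_bins.append(b)
            mixable |= in_bin
        else:
            discarded.extend(sample_ids[in_bin].tolist())
    if not mixable.any():
        warnings.warn("no bin contains both groups; all samples discarded")
        return BalancePlan(
            n_bins=n_bins, bin_edges=edges, kept_sample_ids=[],
            discarded_sample_ids=discarded, seed=seed,
            bin_assignment=pd.Series(assignment, index=sample_ids),
        )
    target = is_ad[mixable].mean()
    for b in mixed_bins:
        in_bin = assignment == b
        ad_ids = sample_ids[in_bin & is_ad]
        ct_ids = sample_ids[in_bin & ~is_ad]
        a, c = len(ad_ids), len(ct_ids)
        frac = a / (a + c)
        if frac > target:
            # discard AD samples; choose the discard count minimizing |frac - target|
            best_k = min(range(a), key=lambda k: (abs((a - k) / (a - k + c) - target), k))
            drop = rng.choice(ad_ids, size=best_k, replace=False) if best_k else np.array([], dtype=ad_ids.dtype)
        elif frac < target:
            best_k = min(range(c), key=lambda k: (abs(a / (a + c - k) - target), k))
            drop = rng.choice(ct_ids, size=best_k, replace=False) if best_k else np.array([], dtype=ct_ids.dtype)
        else:
            drop = np.array([], dtype=sample_ids.dtype)
        drop_set = set(drop.tolist())
        discarded.extend(sorted(drop_set))
        kept.extend([s for s in sample_ids[in_bin] if s not in drop_set])

    return BalancePlan(
        n_bins=n_bins,
        bin_edges=edges,
        kept_sample_ids=kept,
        discarded_sample_ids=discarded,
        seed=seed,
        bin_assignment=pd.Series(assignment, index=sample_ids),
    )


def compare_groups(
    scores: ScoreTable,
    groups: pd.Series | SampleTable,
    group_a: str = "control",
    group_b: str = "AD",
    variant: str = "student",
) -> GroupComparison:
    """delta = mean(group_b) - mean(group_a) with a two-sided t-test p.

    ``variant`` is ``student`` (pooled variance, the default throughout) or
    ``welch``.  Zero variance in both groups with equal means yields p = 1.
    """
    if isinstance(groups, SampleTable):
        groups = groups["diagnosis"]
    groups = groups.loc[scores.scores.index]
    x = scores.scores[groups == group_a].to_numpy(dtype=float)
    y = scores.scores[groups == group_b].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per group")
    delta = float(y.mean() - x.mean())
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        p = 1.0
    else:
        res = stats.ttest_ind(y, x, equal_var=(variant == "student"))
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0
    return GroupComparison(delta=delta, p_value=p, group_sizes=(len(x), len(y)), variant=variant)


def stratify_scores(scores: ScoreTable, by: pd.Series, levels: list[str]) -> dict[str, ScoreTable]:
    """Partition a score table by a covariate level (e.g. Braak stage); no re-centering."""
    by = by.loc[scores.scores.index]
    unknown = set(by.unique()) - set(levels)
    if unknown:
        raise ValueError(f"samples with unknown level(s): {sorted(unknown)}")
    out = {}
    for lev in levels:
        ids = by.index[by == lev]
        if len(ids) == 0:
            warnings.warn(f"level {lev!r} has no samples")
        out[lev] = scores.subset(ids)
    return out
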