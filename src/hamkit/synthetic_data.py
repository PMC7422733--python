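"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators cover every input kind the pipeline consumes:

* sorted-cell bulk counts — negative-binomial gene counts for a cohort of
  15 control / 10 AD purified-microglia profiles, with cell-type marker
  blocks and a planted multiplicative AD effect on designated genes;
* whole-tissue profiles — convex mixtures of cell-type signatures whose
  myeloid mixing weight is drawn from diagnosis-specific distributions
  (control mean 0.10, AD mean 0.20), planting the composition confound that
  myeloid balancing is designed to remove;
* cell-level UMI counts — per-cell multinomial draws with lognormal depth,
  dedicated mitochondrial genes with beta-distributed mito fraction, so some
  cells fail QC by construction;
* qPCR plates — duplicate Cts linear in -log2(expression) with Gaussian
  replicate noise and a detection ceiling recorded as the 999 sentinel.

The negative binomial is parameterized by mean mu and dispersion alpha with
variance mu + alpha * mu^2.  All randomness flows through counter-based
Philox generators keyed by (seed, stream tag), so a fixed seed reproduces
byte-identical outputs, and the ground truth (planted effects, myeloid
weights) is always returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import CellMatrix, ExpressionMatrix, SampleTable
from .qpcr import QpcrPlate, UNDETECTED_CT

# stream tags keep the four generators' random streams independent
_STREAM_SORTED, _STREAM_TISSUE, _STREAM_CELLS, _STREAM_QPCR = 11, 13, 17, 19


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults mirror the study conditions."""

    seed: int
    n_genes: int = 2000
    n_control: int = 15
    n_ad: int = 10
    n_control_tissue: int = 42
    n_ad_tissue: int = 158
    cell_types: dict[str, list[str]] = None  # type -> marker gene ids
    sorted_cell_type: str = "microglia"
    planted_effects: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    base_mean_log: tuple[float, float] = (np.log(100.0), 1.0)  # lognormal of gene means
    marker_log2_elevation: float = 4.0
    myeloid_fraction_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (0.10, 0.05), "AD": (0.20, 0.05)}
    )
    # cell-level parameters
    n_cells: int = 500
    n_cell_samples: int = 6
    depth_lognormal: tuple[float, float] = (np.log(1000.0), 0.5)
    mito_fraction_params: tuple[float, float] = (1.0, 99.0)
    n_mito_genes: int = 10
    # qPCR: Ct = a - b * log2(expr) + N(0, noise_sd); Ct > ceiling -> undetected
    qpcr_intercept: float = 40.0
    qpcr_slope: float = 1.0
    qpcr_noise_sd: float = 0.25
    qpcr_ceiling: float = 35.0

    def __post_init__(self) -> None:
        if self.cell_types is None:
            genes = self.gene_ids()
            n_marker = min(50, self.n_genes // 4)
            self.cell_types = {
                "microglia": genes[:n_marker],
                "neuron": genes[n_marker : 2 * n_marker],
                "astrocyte": genes[2 * n_marker : 3 * n_marker],
            }
        for g, fc in self.planted_effects.items():
            if not np.isfinite(fc):
                raise ValueError(f"planted effect for {g!r} is not finite")
        for dx, (mu, sd) in self.myeloid_fraction_params.items():
            if not (0 <= mu <= 1):
                raise ValueError(f"myeloid fraction mean for {dx!r} outside [0, 1]")
            if sd < 0:
                raise ValueError("myeloid fraction sd must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def mito_gene_ids(self) -> list[str]:
        return [f"MT-{i:02d}" for i in range(self.n_mito_genes)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([config.seed, stream])))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2, via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _base_means(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    mu, sigma = config.base_mean_log
    means = rng.lognormal(mu, sigma, size=config.n_genes)
    return pd.Series(means, index=config.gene_ids())


def _metadata(rng: np.random.Generator, sample_ids, diagnosis) -> SampleTable:
    n = len(sample_ids)
    is_ad = np.array([d == "AD" for d in diagnosis])
    age = np.clip(rng.normal(80, 8, n), 55, 100).round(1)
    sex = np.where(rng.random(n) < 0.55, "M", "F")
    pmi = np.clip(rng.lognormal(np.log(3.0), 0.25, n), 0.5, 10).round(2)
    apoe4 = np.where(is_ad, rng.random(n) < 0.45, rng.random(n) < 0.05)
    braak = np.where(is_ad, rng.integers(5, 7, n), rng.integers(0, 4, n))
    return SampleTable(
        pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "age": age,
                "sex": sex,
                "pmi": pmi,
                "apoe4": apoe4,
                "braak": braak,
                "region": "SFG",
                "cell_type": "microglia",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


def simulate_sorted_counts(config: SimConfig) -> tuple[ExpressionMatrix, SampleTable]:
    """Bulk sorted-cell NB counts with marker elevation and planted AD effects."""
    rng = _rng(config, _STREAM_SORTED)
    means = _base_means(config, rng)
    markers = config.cell_types.get(config.sorted_cell_type, [])
    means.loc[[g for g in markers if g in means.index]] *= 2.0**config.marker_log2_elevation

    n = config.n_control + config.n_ad
    sample_ids = [f"s{i:03d}" for i in range(n)]
    diagnosis = ["control"] * config.n_control + ["AD"] * config.n_ad
    mean_mat = np.tile(means.to_numpy()[:, None], (1, n))
    for g, fc in config.planted_effects.items():
        if g in means.index:
            i = means.index.get_loc(g)
            mean_mat[i, config.n_control :] *= 2.0**fc
    counts = _nb_draw(rng, mean_mat, config.dispersion)
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts.astype(float), index=means.index, columns=sample_ids),
        layer="counts",
    )
    return expr, _metadata(rng, sample_ids, diagnosis)


def make_cell_signatures(config: SimConfig) -> ExpressionMatrix:
    """Per-cell-type mean expression profiles (genes x cell types)."""
    rng = _rng(config, _STREAM_TISSUE * 101)
    means = _base_means(config, rng)
    sig = {}
    for ctype, markers in config.cell_types.items():
        prof = means.copy()
        prof.loc[[g for g in markers if g in prof.index]] *= 2.0**config.marker_log2_elevation
        sig[ctype] = prof
    return ExpressionMatrix(values=pd.DataFrame(sig), layer="nrpkm")


def simulate_whole_tissue(
    config: SimConfig, cell_signatures: ExpressionMatrix | None = None
) -> tuple[ExpressionMatrix, SampleTable, pd.Series]:
    """Whole-tissue NB counts as mixtures confounding myeloid fraction with diagnosis.

    Each sample's mean profile is a convex combination of the cell-type
    signatures; the myeloid weight is drawn from the diagnosis-specific
    normal (clipped to [0.01, 0.95]) and returned as ground truth.  Planted
    effects multiply AD samples' mixture means.
    """
    if cell_signatures is None:
        cell_signatures = make_cell_signatures(config)
    missing = set(config.cell_types) - set(cell_signatures.sample_ids)
    if missing:
        raise ValueError(f"signatures missing for cell types: {sorted(missing)}")
    myeloid = config.sorted_cell_type
    others = [t for t in config.cell_types if t != myeloid]
    rng = _rng(config, _STREAM_TISSUE)

    n = config.n_control_tissue + config.n_ad_tissue
    sample_ids = [f"t{i:03d}" for i in range(n)]
    diagnosis = ["control"] * config.n_control_tissue + ["AD"] * config.n_ad_tissue
    weights = np.empty(n)
    for i, dx in enumerate(diagnosis):
        mu, sd = config.myeloid_fraction_params[dx]
        weights[i] = np.clip(rng.normal(mu, sd), 0.01, 0.95)

    sig = cell_signatures.values
    other_mix = sig[others].mean(axis=1).to_numpy() if others else np.zeros(len(sig))
    mean_mat = (
        weights[None, :] * sig[myeloid].to_numpy()[:, None]
        + (1 - weights)[None, :] * other_mix[:, None]
    )
    for g, fc in config.planted_effects.items():
        if g in sig.index:
            i = sig.index.get_loc(g)
            mean_mat[i, config.n_control_tissue :] *= 2.0**fc
    counts = _nb_draw(rng, mean_mat, config.dispersion)
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts.astype(float), index=sig.index, columns=sample_ids),
        layer="counts",
    )
    meta = _metadata(rng, sample_ids, diagnosis)
    return expr, meta, pd.Series(weights, index=sample_ids, name="myeloid_weight")


def simulate_cells(config: SimConfig) -> CellMatrix:
    """Per-cell multinomial UMI counts with lognormal depth and beta mito fraction."""
    rng = _rng(config, _STREAM_CELLS)
    means = _base_means(config, rng)
    gene_ids = list(means.index) + config.mito_gene_ids()
    n_genes = len(gene_ids)

    n_half = config.n_cell_samples // 2
    samples = [f"c{i:02d}" for i in range(config.n_cell_samples)]
    dx_of = {s: ("control" if i < config.n_cell_samples - n_half else "AD")
             for i, s in enumerate(samples)}
    cell_samples = rng.choice(samples, size=config.n_cells)
    types = list(config.cell_types)
    # microglia-heavy mixture: the aggregated cluster dominates
    probs = np.full(len(types), 0.2 / max(1, len(types) - 1))
    probs[types.index(config.sorted_cell_type)] = 0.8 if len(types) > 1 else 1.0
    cell_types = rng.choice(types, size=config.n_cells, p=probs / probs.sum())

    # per-(diagnosis, type) gene probability vectors over non-mito genes
    prof: dict[tuple[str, str], np.ndarray] = {}
    for ctype, markers in config.cell_types.items():
        base = means.copy()
        base.loc[[g for g in markers if g in base.index]] *= 2.0**config.marker_log2_elevation
        for dx in ("control", "AD"):
            p = base.to_numpy().copy()
            if dx == "AD":
                for g, fc in config.planted_effects.items():
                    if g in base.index:
                        p[base.index.get_loc(g)] *= 2.0**fc
            prof[(dx, ctype)] = p / p.sum()

    mu, sigma = config.depth_lognormal
    depths = np.maximum(1, rng.lognormal(mu, sigma, config.n_cells).astype(int))
    a, b = config.mito_fraction_params
    mito_frac = rng.beta(a, b, config.n_cells)
    n_mito = config.n_mito_genes
    mito_p = np.full(n_mito, 1.0 / n_mito) if n_mito else np.array([])

    rows, cols, data = [], [], []
    for j in range(config.n_cells):
        p = np.empty(n_genes)
        p[: config.n_genes] = (1 - mito_frac[j]) * prof[(dx_of[cell_samples[j]], cell_types[j])]
        if n_mito:
            p[config.n_genes :] = mito_frac[j] * mito_p
        draw = rng.multinomial(depths[j], p / p.sum())
        nz = np.flatnonzero(draw)
        rows.extend(nz.tolist())
        cols.extend([j] * len(nz))
        data.extend(draw[nz].tolist())

    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(n_genes, config.n_cells), dtype=np.int64
    )
    cell_ids = [f"cell{j:05d}" for j in range(config.n_cells)]
    return CellMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_sample=pd.Series(cell_samples, index=cell_ids),
        cell_type=pd.Series(cell_types, index=cell_ids),
        mito_genes=set(config.mito_gene_ids()),
    )


def cell_sample_diagnosis(config: SimConfig) -> pd.Series:
    """Ground-truth diagnosis per single-cell sample (last half of samples are AD)."""
    n_half = config.n_cell_samples // 2
    samples = [f"c{i:02d}" for i in range(config.n_cell_samples)]
    return pd.Series(
        ["control" if i < config.n_cell_samples - n_half else "AD"
         for i in range(config.n_cell_samples)],
        index=samples,
    )


def simulate_qpcr(config: SimConfig, expression: ExpressionMatrix) -> QpcrPlate:
    """Duplicate Cts linear in -log2(expression) with noise and a detection ceiling.

    Zero expression, or a noisy Ct exceeding the ceiling, is recorded as the
    999 sentinel with quality 0.
    """
    rng = _rng(config, _STREAM_QPCR)
    records = []
    vals = expression.values
    for assay in vals.index:
        for sample in vals.columns:
            expr = vals.at[assay, sample]
            for rep in (1, 2):
                if expr <= 0:
                    ct, quality = UNDETECTED_CT, 0.0
                else:
                    ct = (
                        config.qpcr_intercept
                        - config.qpcr_slope * np.log2(expr)
                        + rng.normal(0, config.qpcr_noise_sd)
                    )
                    if ct > config.qpcr_ceiling:
                        ct, quality = UNDETECTED_CT, 0.0
                    else:
                        quality = 1.0
                records.append(
                    {"sample_id": sample, "assay_id": assay, "replicate": rep,
                     "ct": float(ct), "quality": quality}
                )
    return QpcrPlate(pd.DataFrame(records))
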