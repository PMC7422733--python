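"""Shared domain types and readers/writers for the tabular formats the pipeline touches.

Expression matrices are genes x samples pandas DataFrames wrapped with a
declared *layer* so downstream stages can assert they were handed the right
scale (raw counts vs. normalized vs. log-stabilized vs. control-centered).
Cell-level UMI counts are stored sparse (genes x cells) with per-cell sample
and cell-type labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

LAYERS = ("counts", "nrpkm", "normalizedCount", "log2stab", "centered")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared layer.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    The ``counts`` layer must be integer-valued and nonnegative; log layers
    may hold any real values.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if self.layer == "counts":
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise ParseError("counts layer must be integer-valued and >= 0")
        elif self.layer in ("nrpkm", "normalizedCount"):
            if np.any(arr < 0):
                raise ParseError(f"{self.layer} layer must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, layer: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, layer=layer or self.layer)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, float_format="%.12g")


@dataclass
class SampleTable:
    """Per-sample covariates (diagnosis, age, sex, PMI, ApoE4, Braak, ...)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ParseError("duplicate sample ids in sample table")
        for col, lo, hi in (("age", 0, None), ("pmi", 0, None), ("braak", 0, 6)):
            if col in self.data.columns:
                vals = pd.to_numeric(self.data[col], errors="coerce").dropna()
                if (vals < lo).any() or (hi is not None and (vals > hi).any()):
                    raise ParseError(f"{col} values outside allowed range")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)])

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path)


@dataclass
class GeneSet:
    """Named gene list with per-gene direction weight in {+1, -1}.

    A *plain* set has every weight +1; a signed (DE-score) set weights
    up-regulated members +1 and down-regulated members -1.
    """

    name: str
    members: list[str]
    direction: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        if not self.direction:
            self.direction = {g: 1 for g in self.members}
        missing = [g for g in self.members if g not in self.direction]
        if missing:
            raise ValueError(f"gene set {self.name!r}: members without direction: {missing}")
        bad = {g: w for g, w in self.direction.items() if w not in (1, -1)}
        if bad:
            raise ValueError(f"gene set {self.name!r}: directions must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def is_plain(self) -> bool:
        return all(self.direction[g] == 1 for g in self.members)


@dataclass
class CellMatrix:
    """Sparse cell-level UMI counts with per-cell sample/cell-type labels.

    ``counts`` is genes x cells (gene i, cell j holds the raw UMI count
    n_ij).  ``mito_genes`` is the subset of gene ids counted toward the
    per-cell mitochondrial fraction.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_sample: pd.Series
    cell_type: pd.Series
    mito_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ParseError("counts shape does not match gene/cell id lists")
        if len(set(self.gene_ids)) != n_genes:
            raise ParseError("duplicate gene ids in cell matrix")
        if len(set(self.cell_ids)) != n_cells:
            raise ParseError("duplicate cell ids in cell matrix")
        for name, series in (("sample", self.cell_sample), ("cell type", self.cell_type)):
            missing = [c for c in self.cell_ids if c not in series.index]
            if missing:
                raise ParseError(f"cells without a {name} label: {missing}")
        self.cell_sample = self.cell_sample.loc[self.cell_ids]
        self.cell_type = self.cell_type.loc[self.cell_ids]
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ParseError("negative UMI counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def total_umis(self) -> np.ndarray:
        """Per-cell total UMI counts (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of UMIs from mitochondrial genes (0 where total is 0)."""
        totals = self.total_umis()
        mask = np.asarray([g in self.mito_genes for g in self.gene_ids])
        if not mask.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        return frac

    def subset_cells(self, keep: np.ndarray | Sequence[str]) -> "CellMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in keep], dtype=int)
        cell_ids = [self.cell_ids[i] for i in idx]
        return CellMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=cell_ids,
            cell_sample=self.cell_sample.loc[cell_ids],
            cell_type=self.cell_type.loc[cell_ids],
            mito_genes=set(self.mito_genes),
        )

    def subset_genes(self, genes: Sequence[str]) -> "CellMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CellMatrix(
            counts=self.counts[idx, :],
            gene_ids=list(genes),
            cell_ids=list(self.cell_ids),
            cell_sample=self.cell_sample,
            cell_type=self.cell_type,
            mito_genes={g for g in self.mito_genes if g in set(genes)},
        )


@dataclass
class ContingencyTable2x2:
    """2x2 group x status count table for exact tests."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("contingency table entries must be >= 0")
        if self.counts.sum() == 0:
            raise ValueError("contingency table must have at least one positive margin")


# ---------------------------------------------------------------------------
# readers / writers


def _detect_delimiter(path: str | Path) -> str:
    """Auto-detect comma vs tab; ambiguous headers (both present) are rejected."""
    with open(path) as fh:
        header = fh.readline()
    has_comma, has_tab = "," in header, "\t" in header
    if has_comma and has_tab:
        raise ParseError(f"{path}: header contains both ',' and tab; delimiter ambiguous")
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    raise ParseError(f"{path}: could not detect delimiter (no ',' or tab in header)")


def read_expression(path: str | Path, layer: str) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix: first column gene ids, header sample ids."""
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene {bad.index[0]!r}, column {col!r}"
            )
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, layer=layer)


def read_sample_table(path: str | Path) -> SampleTable:
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return SampleTable(df)


def read_gene_sets(path: str | Path, format: str = "gmt") -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...) or two-column text.

    Two-column format: one line per gene, ``gene<sep>+1|-1``; the whole file is
    one set named after the file stem.  Empty sets are skipped with a warning.
    """
    sets: list[GeneSet] = []
    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: GMT line needs name and description")
                name, members = parts[0], [g for g in parts[2:] if g]
                if not members:
                    warnings.warn(f"gene set {name!r} is empty; skipped")
                    continue
                sets.append(GeneSet(name=name, members=members))
    elif format == "two_column":
        name = Path(path).stem
        sep = _detect_delimiter(path)
        members: list[str] = []
        direction: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                gene, tok = [p.strip() for p in line.split(sep)][:2]
                if tok in ("+1", "1"):
                    w = 1
                elif tok in ("-1", "−1"):
                    w = -1
                else:
                    raise ParseError(f"{path}:{lineno}: unknown direction token {tok!r}")
                members.append(gene)
                direction[gene] = w
        if not members:
            warnings.warn(f"gene set {name!r} is empty; skipped")
        else:
            sets.append(GeneSet(name=name, members=members, direction=direction))
    else:
        raise ValueError(f"unknown gene set format {format!r}")
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, ""] + list(gs.members)) + "\n")


def read_cell_matrix(
    path: str | Path,
    metadata: str | Path,
    format: str = "mtx_triplet",
    mito_prefix: str = "MT-",
) -> CellMatrix:
    """Read cell-level UMI counts plus a cell metadata table.

    ``mtx_triplet`` expects ``<path>`` to be a MatrixMarket file with sidecar
    id lists ``<path stem>.genes.txt`` and ``<path stem>.cells.txt`` (one id
    per line, genes as rows).  ``dense_csv`` expects genes as rows and cell
    ids in the header.  ``metadata`` is a CSV with columns cell_id, sample,
    cell_type; every cell in the counts must appear in it.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mat = sp.csr_matrix(scipy.io.mmread(path))
        stem = path.with_suffix("")
        gene_ids = Path(f"{stem}.genes.txt").read_text().split()
        cell_ids = Path(f"{stem}.cells.txt").read_text().split()
    elif format == "dense_csv":
        df = pd.read_csv(path, sep=_detect_delimiter(path), index_col=0)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        mat = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown cell matrix format {format!r}")

    meta = pd.read_csv(metadata, sep=_detect_delimiter(metadata))
    meta["cell_id"] = meta["cell_id"].astype(str)
    meta = meta.set_index("cell_id")
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ParseError(f"cells missing from metadata: {missing}")
    mito = {g for g in gene_ids if g.startswith(mito_prefix)}
    return CellMatrix(
        counts=mat,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_sample=meta["sample"].astype(str),
        cell_type=meta["cell_type"].astype(str),
        mito_genes=mito,
    )


def write_cell_matrix(cells: CellMatrix, path: str | Path) -> None:
    """Write a CellMatrix as MatrixMarket triplets plus sidecar id/metadata files."""
    path = Path(path)
    scipy.io.mmwrite(str(path), sp.coo_matrix(cells.counts))
    stem = path.with_suffix("")
    Path(f"{stem}.genes.txt").write_text("\n".join(cells.gene_ids) + "\n")
    Path(f"{stem}.cells.txt").write_text("\n".join(cells.cell_ids) + "\n")
    meta = pd.DataFrame(
        {"cell_id": cells.cell_ids,
         "sample": cells.cell_sample.values,
         "cell_type": cells.cell_type.values}
    )
    meta.to_csv(f"{stem}.metadata.csv", index=False)
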