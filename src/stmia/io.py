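"""Readers and writers for the file formats the pipeline touches.

Count matrices travel as MatrixMarket coordinate files plus one-record-per-line
TSV files for gene ids and unit barcodes (the 10x "matrix dir" convention).
Spot coordinates use the Visium ``tissue_positions`` CSV dialect, with or
without the v1 header line.  Gene sets use GMT.  Structured configuration is
YAML (a strict superset of JSON, so ``.json`` files load too).

Internally everything is 0-based; MatrixMarket's 1-based indices exist only on
disk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSet",
    "read_counts",
    "write_counts",
    "read_spot_positions",
    "write_spot_positions",
    "read_gmt",
    "write_gmt",
    "load_config",
]


class FormatError(ValueError):
    """A file violates the expected on-disk format or an invariant."""


POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pixel_row",
    "pixel_col",
]

# Visium v1 header spelling; accepted as an alias for POSITION_COLUMNS.
_VISIUM_V1_HEADER = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise FormatError(f"duplicate {what} id: {dup!r}")


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x units.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    unit_ids
        Unique unit identifiers (spot or cell barcodes), one per column.
    counts
        Non-negative integer matrix of shape ``(len(gene_ids), len(unit_ids))``.
    unit_kind
        ``"spot"`` for spatial arrays, ``"cell"`` for dissociated cells.
    """

    gene_ids: list[str]
    unit_ids: list[str]
    counts: np.ndarray
    unit_kind: str = "spot"

    def __post_init__(self) -> None:
        if self.unit_kind not in ("spot", "cell"):
            raise ValueError(f"unit_kind must be 'spot' or 'cell', got {self.unit_kind!r}")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts contain non-integer entries")
            self.counts = as_int
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts contain negative entries")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.unit_ids, "unit")

    # -- convenience accessors used throughout the pipeline ------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def detected_genes_per_unit(self) -> np.ndarray:
        """Number of genes with count > 0, per unit."""
        return (self.counts > 0).sum(axis=0)

    def total_counts_per_unit(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def mito_gene_mask(self, prefix: str = "MT-") -> np.ndarray:
        return np.array([g.startswith(prefix) for g in self.gene_ids], dtype=bool)

    def mito_fraction_per_unit(self, prefix: str = "MT-") -> np.ndarray:
        """Fraction of each unit's UMIs from mitochondrially encoded genes."""
        mito = self.mito_gene_mask(prefix)
        totals = self.total_counts_per_unit().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.counts[mito].sum(axis=0) / totals
        return np.where(totals > 0, frac, 0.0)

    def subset_units(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            unit_ids=[self.unit_ids[i] for i in index],
            counts=self.counts[:, index],
            unit_kind=self.unit_kind,
        )

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in index],
            unit_ids=list(self.unit_ids),
            counts=self.counts[index, :],
            unit_kind=self.unit_kind,
        )


@dataclass
class GeneSet:
    """A named set of gene identifiers (one GMT record)."""

    name: str
    description: str = ""
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _read_id_column(path: Path, what: str) -> list[str]:
    """First column of a headerless TSV; 1 or 2 columns accepted."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    _check_unique(ids, what)
    return ids


def read_counts(
    matrix_path, genes_path, barcodes_path, unit_kind: str = "spot"
) -> CountMatrix:
    """Read a MatrixMarket count matrix with its gene and barcode TSVs.

    The matrix file must be MatrixMarket coordinate format with integer,
    non-negative entries; its declared shape must match the TSV line counts.
    Genes are rows, units columns (the ST/10x convention).
    """
    gene_ids = _read_id_column(Path(genes_path), "gene")
    unit_ids = _read_id_column(Path(barcodes_path), "unit")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if mat.shape != (len(gene_ids), len(unit_ids)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(gene_ids)} genes "
            f"x {len(unit_ids)} barcodes"
        )
    if not np.issubdtype(mat.dtype, np.integer):
        as_int = np.round(mat).astype(np.int64)
        if not np.allclose(mat, as_int, rtol=0, atol=0):
            raise FormatError("matrix contains non-integer entries")
        mat = as_int
    if mat.size and mat.min() < 0:
        raise FormatError("matrix contains negative entries")
    return CountMatrix(gene_ids, unit_ids, mat.astype(np.int64), unit_kind)


def write_counts(cm: CountMatrix, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` to *out_dir*.

    The MTX payload is coordinate integer format with 1-based indices and an
    exact nnz in the size line.  Returns the three paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    sparse = scipy.sparse.coo_matrix(cm.counts)
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in cm.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in cm.unit_ids))
    return paths


def read_spot_positions(csv_path) -> pd.DataFrame:
    """Read a Visium-dialect tissue-positions CSV.

    Accepts either a headerless 6-column file or the Visium v1 header.
    Returns a typed frame with columns ``barcode, in_tissue, array_row,
    array_col, pixel_row, pixel_col``; pixel coordinates are carried through
    uninterpreted.
    """
    path = Path(csv_path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"empty spot positions file: {path}", stacklevel=2)
        return pd.DataFrame(columns=POSITION_COLUMNS).astype(
            {
                "in_tissue": np.int64,
                "array_row": np.int64,
                "array_col": np.int64,
                "pixel_row": float,
                "pixel_col": float,
            }
        )
    first = text.splitlines()[0].split(",")
    has_header = [c.strip().lower() for c in first[:2]] == ["barcode", "in_tissue"]
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=POSITION_COLUMNS,
        dtype={0: str},
    )
    if df.shape[1] != 6:
        raise FormatError(f"expected 6 columns in {path}, found {df.shape[1]}")
    for col in ("in_tissue", "array_row", "array_col"):
        vals = df[col].to_numpy()
        as_int = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(as_int)) or not np.array_equal(as_int, np.floor(as_int)):
            raise FormatError(f"non-integer values in column {col!r} of {path}")
        df[col] = as_int.astype(np.int64)
    if not df["in_tissue"].isin([0, 1]).all():
        bad = df.loc[~df["in_tissue"].isin([0, 1]), "in_tissue"].iloc[0]
        raise FormatError(f"in_tissue must be 0 or 1, got {bad}")
    if (df[["array_row", "array_col"]] < 0).any().any():
        raise FormatError("array coordinates must be >= 0")
    if df["barcode"].duplicated().any():
        raise FormatError("duplicate barcode in spot positions")
    if df.duplicated(subset=["array_row", "array_col"]).any():
        raise FormatError("duplicate (array_row, array_col) position")
    return df


def write_spot_positions(positions: pd.DataFrame, csv_path, header: bool = False) -> Path:
    path = Path(csv_path)
    positions.to_csv(path, index=False, header=header, columns=POSITION_COLUMNS)
    return path


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Duplicate genes within one record collapse silently (a set is a set).
    A record with fewer than three fields is a format error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT record needs >= 3 fields")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: GMT record has an empty gene list")
            sets.append(GeneSet(name=name, description=description, genes=frozenset(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> Path:
    """Write gene sets as GMT; genes are sorted for reproducible output."""
    path = Path(path)
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n")
    return path


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config root in {path} must be a mapping")
    return cfg
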