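"""Readers, writers, and core containers for expression and coordinate data.

Counts can arrive as a MatrixMarket triplet (matrix + gene-name and
spot-name files, in either orientation), a dense CSV/TSV with a header row,
or an h5ad-dialect HDF5 container. Spots are always rows in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix", "CoordinateTable", "FeatureMatrix",
    "read_counts", "read_coords", "read_labels",
    "write_counts_csv", "write_counts_mtx", "write_coords",
]


class FormatError(ValueError):
    """Raised when an input file does not parse under the named format."""


class AlignmentError(ValueError):
    """Raised when identifier lists and matrix dimensions disagree."""


@dataclass
class CountMatrix:
    """Spots × genes expression matrix with identifiers.

    `values` holds raw counts on input but may hold normalized/log values
    after preprocessing; entries are never negative.
    """

    values: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise ValueError(f"need at least 2 spots and 2 genes, got {n}x{d}")
        if len(self.spot_ids) != n:
            raise AlignmentError(f"{len(self.spot_ids)} spot ids for {n} rows")
        if len(self.gene_ids) != d:
            raise AlignmentError(f"{len(self.gene_ids)} gene ids for {d} columns")
        if len(set(self.spot_ids)) != n:
            raise AlignmentError("duplicate spot identifiers")
        if len(set(self.gene_ids)) != d:
            raise AlignmentError("duplicate gene identifiers")
        if np.any(self.values < 0):
            raise ValueError("negative entries in count matrix")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class CoordinateTable:
    """Spots × 2 spatial coordinates aligned to a CountMatrix spot order."""

    xy: np.ndarray
    spot_ids: list[str]

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must be an N x 2 table")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite coordinates")
        if len(self.spot_ids) != self.xy.shape[0]:
            raise AlignmentError("spot id / coordinate length mismatch")

    def aligned_to(self, spot_ids: list[str]) -> "CoordinateTable":
        """Reorder rows to match the given spot-id order."""
        index = {s: i for i, s in enumerate(self.spot_ids)}
        missing = [s for s in spot_ids if s not in index]
        if missing:
            raise AlignmentError(f"coordinates missing for spots: {missing[:5]}")
        order = [index[s] for s in spot_ids]
        return CoordinateTable(self.xy[order], list(spot_ids))


@dataclass
class FeatureMatrix:
    """Spots × d reduced expression features (default d = 50 PCs)."""

    values: np.ndarray
    d: int = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite features")
        self.d = self.values.shape[1]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_name_file(path) -> list[str]:
    with open(path) as fh:
        names = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return names


def _orient(values, spot_names, gene_names, orientation):
    rows, cols = values.shape
    if orientation == "spots-rows":
        return values
    if orientation == "genes-rows":
        return values.T
    if rows == cols and len(spot_names) == len(gene_names) == rows:
        raise AlignmentError(
            "square matrix with equal-length name files: pass orientation="
            "'spots-rows' or 'genes-rows' explicitly")
    if len(spot_names) == rows and len(gene_names) == cols:
        return values
    if len(gene_names) == rows and len(spot_names) == cols:
        return values.T
    raise AlignmentError(
        f"name-file lengths ({len(spot_names)} spots, {len(gene_names)} genes)"
        f" match neither orientation of a {rows}x{cols} matrix")


def read_counts(path, format: str = "csv", *, spot_file=None, gene_file=None,
                orientation: str | None = None) -> CountMatrix:
    """Read a count matrix; spots are rows in the result regardless of on-disk layout.

    format 'mtx-triplet' requires `spot_file` and `gene_file`; orientation is
    inferred from the name-file lengths (the ambiguous square case needs an
    explicit `orientation`). format 'h5ad-dialect' reads only X, obs names
    and var names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0,
                             sep="\t" if path.suffix in (".tsv", ".txt") else ",")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"could not parse {path} as dense CSV/TSV: {exc}")
        return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))
    if format == "mtx-triplet":
        if spot_file is None or gene_file is None:
            raise ValueError("mtx-triplet requires spot_file and gene_file")
        try:
            values = np.asarray(scipy.io.mmread(path).todense())
        except Exception as exc:
            raise FormatError(f"could not parse {path} as MatrixMarket: {exc}")
        spots = _read_name_file(spot_file)
        genes = _read_name_file(gene_file)
        values = _orient(values, spots, genes, orientation)
        return CountMatrix(values, spots, genes)
    if format == "h5ad-dialect":
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.X
        values = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)
        return CountMatrix(values, list(adata.obs_names), list(adata.var_names))
    raise ValueError(f"unknown format {format!r}")


def read_coords_h5ad(path, obsm_key: str = "spatial") -> CoordinateTable:
    """Coordinates from a named obsm slot of an h5ad-dialect container.

    Only the first two columns of the slot are used; everything else in the
    container is ignored.
    """
    import anndata

    adata = anndata.read_h5ad(path)
    if obsm_key not in adata.obsm:
        raise FormatError(f"obsm slot {obsm_key!r} not found; "
                          f"available: {list(adata.obsm.keys())}")
    xy = np.asarray(adata.obsm[obsm_key])[:, :2]
    return CoordinateTable(xy, list(adata.obs_names))


def read_coords(path) -> CoordinateTable:
    """Read a spot_id,x,y table (CSV or TSV, header required)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    expected = {"spot_id", "x", "y"}
    if not expected.issubset(df.columns):
        raise FormatError(f"coordinate file must have columns {sorted(expected)}, "
                          f"found {list(df.columns)}")
    return CoordinateTable(df[["x", "y"]].to_numpy(), list(df["spot_id"].astype(str)))


def read_labels(path, spot_ids: list[str] | None = None) -> np.ndarray:
    """Read a spot_id,label CSV; optionally reorder to the given spot order."""
    df = pd.read_csv(path)
    if "spot_id" not in df.columns or "label" not in df.columns:
        raise FormatError("label file must have columns spot_id,label")
    df["spot_id"] = df["spot_id"].astype(str)
    if spot_ids is not None:
        df = df.set_index("spot_id").loc[[str(s) for s in spot_ids]].reset_index()
    codes, _ = pd.factorize(df["label"])
    return codes.astype(np.int64)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_counts_csv(counts: CountMatrix, path) -> None:
    pd.DataFrame(counts.values, index=counts.spot_ids,
                 columns=counts.gene_ids).to_csv(path, index_label="spot_id")


def write_counts_mtx(counts: CountMatrix, mtx_path, spot_file, gene_file) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(counts.values))
    Path(spot_file).write_text("".join(f"{s}\n" for s in counts.spot_ids))
    Path(gene_file).write_text("".join(f"{g}\n" for g in counts.gene_ids))


def write_coords(coords: CoordinateTable, path) -> None:
    pd.DataFrame({"spot_id": coords.spot_ids,
                  "x": coords.xy[:, 0], "y": coords.xy[:, 1]}).to_csv(path, index=False)
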