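"""Count-matrix I/O and pseudobulk aggregation.

Reads and writes the 10x-style on-disk layout (Matrix Market triplet file
plus ``features.tsv`` / ``barcodes.tsv`` sidecars, optionally gzipped) and
collapses annotated cells into the per-(animal, cell type) pseudobulk table
of target and total UMI sums that the negative-binomial offset model
consumes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "barcode",
    "animal",
    "treatment",
    "cell_type",
    "region",
    "weeks_post_dose",
]

PSEUDOBULK_COLUMNS = [
    "animal",
    "cell_type",
    "treatment",
    "target_umi",
    "total_umi",
    "n_cells",
]


@dataclass
class CountMatrix:
    """Sparse nonnegative integer UMI matrix, features x cells.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix of shape (n_features, n_cells) with
        nonnegative integer entries.
    feature_ids
        One label per row.
    barcodes
        One label per column.
    """

    values: sp.spmatrix
    feature_ids: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        self.feature_ids = list(self.feature_ids)
        self.barcodes = list(self.barcodes)
        if self.values.shape != (len(self.feature_ids), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match sidecars "
                f"({len(self.feature_ids)} features, {len(self.barcodes)} barcodes)"
            )
        data = self.values.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("count matrix entries must be nonnegative integers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_totals(self) -> np.ndarray:
        """Total UMIs per cell (column sums), as an integer vector."""
        return np.asarray(self.values.sum(axis=0)).ravel().astype(np.int64)

    def feature_row(self, feature_id: str) -> np.ndarray:
        """Dense count vector across cells for one feature."""
        try:
            idx = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return np.asarray(self.values[idx, :].todense()).ravel().astype(np.int64)


def _read_lines(path: Path) -> list[str]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _maybe_gz(path: Path) -> Path:
    """Return *path*, or its .gz sibling if only that exists."""
    if path.exists():
        return path
    gz = Path(str(path) + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(path)


def read_counts(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read a Matrix Market triplet file with TSV sidecars.

    On-disk indices are 1-based (Matrix Market convention); the returned
    matrix is 0-based in memory. Gzip-compressed files are accepted
    transparently. Raises on dimension mismatches, non-integer or negative
    entries, and duplicate (row, col) triplets.
    """
    mtx_path = _maybe_gz(Path(mtx_path))
    features_path = _maybe_gz(Path(features_path))
    barcodes_path = _maybe_gz(Path(barcodes_path))

    raw = scipy.io.mmread(str(mtx_path))
    coo = sp.coo_matrix(raw)
    if coo.nnz:
        keys = coo.row.astype(np.int64) * coo.shape[1] + coo.col
        if np.unique(keys).size != keys.size:
            raise ValueError(f"duplicate (row, col) triplets in {mtx_path}")
        if np.any(coo.data < 0) or np.any(coo.data != np.round(coo.data)):
            raise ValueError(f"non-integer or negative entry in {mtx_path}")
    features = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    # sidecars may carry extra tab-separated columns (10x writes id\tname\ttype)
    features = [f.split("\t")[0] for f in features]
    barcodes = [b.split("\t")[0] for b in barcodes]
    return CountMatrix(coo.astype(np.int64), features, barcodes)


def write_counts(m: CountMatrix, dir_path) -> dict[str, Path]:
    """Write *m* as ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``.

    Returns the paths written. The triplet file uses 1-based indices and an
    integer field, so :func:`read_counts` round-trips exactly.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": dir_path / "matrix.mtx",
        "features": dir_path / "features.tsv",
        "barcodes": dir_path / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(m.values), field="integer")
    paths["matrix"] = Path(str(paths["matrix"]))
    paths["features"].write_text("".join(f + "\n" for f in m.feature_ids))
    paths["barcodes"].write_text("".join(b + "\n" for b in m.barcodes))
    return paths


def read_annotations(path) -> pd.DataFrame:
    """Read a cell-annotation TSV (barcode, animal, treatment, cell_type,
    region, weeks_post_dose). Barcodes must be unique."""
    ann = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if ann["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in annotation table")
    return ann


def write_annotations(ann: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.to_csv(path, sep="\t", index=False)
    return path


def _aligned_annotations(m: CountMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    ann = ann.set_index("barcode", drop=False)
    unannotated = [b for b in m.barcodes if b not in ann.index]
    if unannotated:
        raise ValueError(
            f"{len(unannotated)} barcodes lack annotations "
            f"(first: {unannotated[0]!r})"
        )
    return ann.loc[m.barcodes]


def aggregate_pseudobulk(
    m: CountMatrix, ann: pd.DataFrame, target_feature: str
) -> pd.DataFrame:
    """Collapse cells to per-(animal, cell type) sums of target and total UMIs.

    Cells whose total UMI count is zero carry no exposure for the offset
    model and are dropped with a warning. Returns a DataFrame with columns
    animal, cell_type, treatment, target_umi, total_umi, n_cells — one row
    per (animal, cell_type); grand totals over rows equal the matrix totals
    of the retained cells.
    """
    aligned = _aligned_annotations(m, ann)
    target = m.feature_row(target_feature)
    totals = m.column_totals()

    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d cells with zero total UMIs", n_dropped)

    df = pd.DataFrame(
        {
            "animal": aligned["animal"].to_numpy()[keep],
            "cell_type": aligned["cell_type"].to_numpy()[keep],
            "treatment": aligned["treatment"].to_numpy()[keep],
            "target_umi": target[keep],
            "total_umi": totals[keep],
        }
    )
    grouped = (
        df.groupby(["animal", "cell_type"], sort=True, observed=True)
        .agg(
            treatment=("treatment", "first"),
            n_treatments=("treatment", "nunique"),
            target_umi=("target_umi", "sum"),
            total_umi=("total_umi", "sum"),
            n_cells=("target_umi", "size"),
        )
        .reset_index()
    )
    if (grouped["n_treatments"] > 1).any():
        bad = grouped.loc[grouped["n_treatments"] > 1, "animal"].iloc[0]
        raise ValueError(f"animal {bad!r} annotated with more than one treatment")
    return grouped[PSEUDOBULK_COLUMNS]


def per_cell_target_counts(
    m: CountMatrix, ann: pd.DataFrame, target_feature: str, cell_type: str
) -> list[tuple[int, int]]:
    """Per-cell (target_umi, total_umi) pairs for one cell type.

    Order is stable by barcode (lexicographic). An unknown cell type is an
    error; a known cell type with no cells returns an empty list.
    """
    aligned = _aligned_annotations(m, ann)
    if cell_type not in set(ann["cell_type"]):
        raise KeyError(f"unknown cell type {cell_type!r}")
    target = m.feature_row(target_feature)
    totals = m.column_totals()
    mask = (aligned["cell_type"].to_numpy() == cell_type) & (totals > 0)
    order = np.argsort(np.asarray(m.barcodes, dtype=object)[mask], kind="stable")
    pairs = list(zip(target[mask][order].tolist(), totals[mask][order].tolist()))
    return pairs


def write_pseudobulk(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> Path:
    """Write the pseudobulk table as TSV, optionally with '#'-prefixed
    provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table[PSEUDOBULK_COLUMNS].to_csv(fh, sep="\t", index=False)
    return path


def read_pseudobulk(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PSEUDOBULK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pseudobulk table missing columns: {missing}")
    if (table["target_umi"] > table["total_umi"]).any():
        raise ValueError("target_umi exceeds total_umi")
    return table
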