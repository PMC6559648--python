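"""Readers and writers for the matrix formats the tool touches.

Sparse matrices travel as Matrix Market coordinate files (1-based indices,
``%%MatrixMarket matrix coordinate real general`` header, duplicate
entries summed per the format's convention); dense matrices as comma- or
tab-delimited text with an optional header row.  Factor triples round-trip
through delimited text at full double precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .core import DataMatrix, FactorTriple

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_factors",
    "read_factors",
    "MatrixFormatError",
]


class MatrixFormatError(ValueError):
    """A matrix file failed to parse or violated the non-negativity contract."""


def _check_nonnegative_sparse(M: sp.coo_matrix) -> None:
    if M.nnz and M.data.min() < 0:
        idx = int(np.argmin(M.data))
        raise MatrixFormatError(
            f"negative entry {M.data[idx]} at row {M.row[idx] + 1}, "
            f"column {M.col[idx] + 1} (1-based)"
        )


def _read_mtx(path: Path) -> DataMatrix:
    try:
        M = scipy.io.mmread(os.fspath(path))
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise MatrixFormatError(f"failed to parse Matrix Market file {path}: {exc}") from exc
    M = sp.coo_matrix(M)
    M.sum_duplicates()
    _check_nonnegative_sparse(M)
    return DataMatrix(M.tocsr())


def _read_delimited(path: Path) -> DataMatrix:
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    start = 0
    try:
        [float(tok) for tok in lines[0].strip().split(delim)]
    except ValueError:
        start = 1  # header row
    width = None
    for lineno in range(start, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        toks = line.split(delim)
        try:
            row = [float(tok) for tok in toks]
        except ValueError as exc:
            raise MatrixFormatError(
                f"{path}: line {lineno + 1}: cannot parse {exc}"
            ) from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise MatrixFormatError(
                f"{path}: line {lineno + 1}: expected {width} columns, got {len(row)}"
            )
        for j, v in enumerate(row):
            if v < 0:
                raise MatrixFormatError(
                    f"negative entry {v} at row {lineno + 1 - start}, "
                    f"column {j + 1} (1-based)"
                )
        rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    return DataMatrix(np.array(rows, dtype=float))


def read_matrix(path, format: str = "auto") -> DataMatrix:
    """Read a non-negative matrix from disk.

    ``format`` is one of ``auto`` (by extension: ``.mtx`` is Matrix
    Market, anything else delimited text), ``mtx``, or ``delimited``.
    Matrix Market input yields sparse storage, delimited input dense.
    Negative values are rejected with the offending coordinate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mtx" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "mtx":
        return _read_mtx(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(X: DataMatrix, path) -> None:
    """Write a DataMatrix: Matrix Market for sparse storage, CSV for dense."""
    path = Path(path)
    if X.is_sparse:
        scipy.io.mmwrite(os.fspath(path), X.values)
    else:
        np.savetxt(path, X.values, delimiter=",", fmt="%.17g")


def _factor_paths(prefix) -> dict[str, Path]:
    prefix = Path(prefix)
    return {name: prefix.parent / f"{prefix.name}.{name}.csv" for name in ("U", "S", "V")}


def write_factors(F: FactorTriple, prefix) -> dict[str, Path]:
    """Write U, S, V as ``<prefix>.U.csv`` etc. at full double precision.

    The target directory must exist; nothing is written otherwise.
    Returns the mapping of factor name to file path.
    """
    paths = _factor_paths(prefix)
    parent = Path(prefix).parent
    if not parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {parent}")
    for name, mat in (("U", F.U), ("S", F.S), ("V", F.V)):
        np.savetxt(paths[name], mat, delimiter=",", fmt="%.17g")
    return paths


def read_factors(prefix) -> FactorTriple:
    """Read a factor triple written by :func:`write_factors`."""
    paths = _factor_paths(prefix)
    mats = {
        name: np.loadtxt(p, delimiter=",", ndmin=2) for name, p in paths.items()
    }
    return FactorTriple(mats["U"], mats["S"], mats["V"])
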