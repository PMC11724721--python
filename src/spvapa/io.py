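"""Readers and writers for the on-disk formats the pipeline consumes.

Count matrices travel as Matrix Market (.mtx) with sidecar row/column name
files (one id per line) or as dense CSV with row index and column header.
Site annotations are 6-column BED whose name field packs
``site_id|gene_id|region``.  phi matrices are CSV with missing entries left
empty.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .apa_matrix import ExprMatrix, PhiMatrix, SiteAnnotation, SiteCounts


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def read_matrix(path: str | Path) -> tuple[np.ndarray | sparse.spmatrix, list[str], list[str]]:
    """Read a matrix from .mtx (+ sidecar name files) or dense CSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path).tocsr()
        rows_path, cols_path = _sidecar_paths(path)
        row_ids = rows_path.read_text().split()
        col_ids = cols_path.read_text().split()
        return mat, row_ids, col_ids
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_matrix(mat, row_ids, col_ids, path: str | Path) -> None:
    """Write a matrix to .mtx (+ sidecars) or dense CSV, by extension."""
    path = Path(path)
    if path.suffix == ".mtx":
        m = sparse.coo_matrix(mat)
        spio.mmwrite(path, m)
        rows_path, cols_path = _sidecar_paths(path)
        rows_path.write_text("\n".join(row_ids) + "\n")
        cols_path.write_text("\n".join(col_ids) + "\n")
    else:
        dense = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
        pd.DataFrame(dense, index=row_ids, columns=col_ids).to_csv(path)


def read_site_counts(path: str | Path) -> SiteCounts:
    mat, site_ids, cell_ids = read_matrix(path)
    return SiteCounts(mat, site_ids, cell_ids)


def read_expr(path: str | Path) -> ExprMatrix:
    mat, gene_ids, cell_ids = read_matrix(path)
    return ExprMatrix(mat, gene_ids, cell_ids)


def read_sites_bed(path: str | Path) -> list[SiteAnnotation]:
    """Parse a 6-column BED of poly(A) sites; name = site_id|gene_id|region."""
    out: list[SiteAnnotation] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"BED line has {len(fields)} fields, need 6: {line!r}")
        chrom, start, end, name, _score, strand = fields[:6]
        parts = name.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"BED name field must be 'site_id|gene_id|region', got {name!r}"
            )
        site_id, gene_id, region = parts
        out.append(
            SiteAnnotation(site_id, chrom, int(start), int(end), strand, gene_id, region)
        )
    return out


def write_sites_bed(sites: list[SiteAnnotation], path: str | Path) -> None:
    lines = [
        f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}|{s.gene_id}|{s.region}\t0\t{s.strand}"
        for s in sites
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_phi_csv(path: str | Path) -> PhiMatrix:
    """Read a phi matrix from CSV; empty cells are missing entries."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    return PhiMatrix(
        values, [str(i) for i in df.index], [str(c) for c in df.columns], np.isnan(values)
    )


def write_phi_csv(phi: PhiMatrix, path: str | Path) -> None:
    phi.to_frame().to_csv(path, na_rep="")


def write_phi_mtx(phi: PhiMatrix, path: str | Path) -> None:
    """Write phi values and missing mask as a .mtx pair (<stem>.mask.mtx)."""
    path = Path(path)
    vals = np.where(phi.mask, 0.0, phi.values)
    write_matrix(vals, phi.gene_ids, phi.cell_ids, path)
    mask_path = path.with_suffix("").with_suffix(".mask.mtx")
    spio.mmwrite(mask_path, sparse.coo_matrix(phi.mask.astype(int)))


def read_labels(path: str | Path, column: str = "label") -> pd.DataFrame:
    """Read a cell/spot metadata table (TSV/CSV) indexed by cell id.

    Must contain a categorical label column; optional ``x``/``y`` spatial
    coordinate columns are preserved.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if column not in df.columns:
        raise ValueError(f"metadata file {path} lacks a {column!r} column")
    return df
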