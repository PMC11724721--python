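"""Construction of the APA usage (phi) matrix from poly(A)-site counts.

Alternative polyadenylation (APA) produces mRNA isoforms differing in their
3' ends.  For a gene with two or more poly(A) sites in its 3' UTR, the
relative usage of the distal-most site (RUD, here ``phi``) summarises, per
cell or spot, how often the long 3' UTR isoform is chosen:

    phi(g, c) = reads at the distal-most 3' UTR site of g in cell c
                / total reads over all 3' UTR sites of g in cell c

phi lies in [0, 1]; cells where the gene attracts fewer than ``min_total``
reads carry no information about site choice and are recorded as *missing*
(an explicit mask — never 0, which is a valid phi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class SiteAnnotation:
    """One poly(A) site: BED-style half-open coordinates plus gene context."""

    site_id: str
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str
    gene_id: str
    region: str = "3UTR"  # "3UTR" or "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"site {self.site_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-'")


@dataclass
class SiteCounts:
    """Poly(A)-site x cell read-count matrix (sparse or dense)."""

    counts: sparse.spmatrix | np.ndarray
    site_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        n_sites, n_cells = self.counts.shape
        if n_sites != len(self.site_ids) or n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} site ids x {len(self.cell_ids)} cell ids"
            )
        if self.counts.min() < 0:
            raise ValueError("site counts must be non-negative")

    def row(self, site_id: str) -> np.ndarray:
        i = self.site_ids.index(site_id)
        r = self.counts[i]
        return np.asarray(r.todense()).ravel() if sparse.issparse(r) else np.asarray(r).ravel()


@dataclass
class PhiMatrix:
    """Gene x cell RUD matrix with an explicit missing-entry mask.

    ``values[i, j]`` is meaningful only where ``mask[i, j]`` is False;
    masked positions hold NaN.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    mask: np.ndarray = field(default=None)  # True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match id lists")
        obs = self.values[~self.mask]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 1):
            raise ValueError("non-missing phi values must lie in [0, 1]")
        # canonical representation: NaN under the mask
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def missing_rate(self) -> float:
        return float(self.mask.mean())

    def copy(self) -> "PhiMatrix":
        return PhiMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), self.mask.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ExprMatrix:
    """Gene x cell expression count matrix (the G matrix)."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match id lists")
        if self.counts.min() < 0:
            raise ValueError("expression counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


def filter_apa_genes(sites: list[SiteAnnotation]) -> dict[str, list[SiteAnnotation]]:
    """Retain 3' UTR-APA genes and order their sites proximal -> distal.

    A gene qualifies when it has at least two poly(A) sites annotated to its
    3' UTR.  Site order follows the direction of transcription: on the plus
    strand the distal site has the larger genomic coordinate, on the minus
    strand the smaller one.  Genes whose 3' UTR sites sit on both strands are
    ambiguous and are dropped with a warning.
    """
    seen: set[str] = set()
    for s in sites:
        if s.site_id in seen:
            raise ValueError(f"duplicate site_id {s.site_id!r}")
        seen.add(s.site_id)

    by_gene: dict[str, list[SiteAnnotation]] = {}
    for s in sites:
        if s.region == "3UTR":
            by_gene.setdefault(s.gene_id, []).append(s)

    out: dict[str, list[SiteAnnotation]] = {}
    for gene_id, gsites in by_gene.items():
        if len(gsites) < 2:
            continue
        strands = {s.strand for s in gsites}
        if len(strands) > 1:
            warnings.warn(
                f"gene {gene_id!r}: 3' UTR sites on mixed strands, gene rejected",
                stacklevel=2,
            )
            continue
        reverse = gsites[0].strand == "-"
        out[gene_id] = sorted(gsites, key=lambda s: s.start, reverse=reverse)
    return out


def compute_phi(
    counts: SiteCounts,
    gene_sites: dict[str, list[SiteAnnotation]],
    min_total: int = 1,
) -> PhiMatrix:
    """Compute the RUD matrix: distal-site reads over total 3' UTR reads.

    Parameters
    ----------
    counts
        Site-level read counts.
    gene_sites
        Output of :func:`filter_apa_genes`; per gene, sites ordered
        proximal -> distal so the last entry is the distal-most site.
    min_total
        Minimum total read count over a gene's 3' UTR sites for phi to be
        considered observed in a cell; below it the entry is missing.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")

    mat = counts.counts
    if sparse.issparse(mat):
        mat = np.asarray(mat.todense())
    mat = np.asarray(mat, dtype=float)
    site_index = {sid: i for i, sid in enumerate(counts.site_ids)}

    gene_ids = sorted(gene_sites)
    n_cells = len(counts.cell_ids)
    values = np.full((len(gene_ids), n_cells), np.nan)

    for gi, gene_id in enumerate(gene_ids):
        gsites = gene_sites[gene_id]
        try:
            rows = [site_index[s.site_id] for s in gsites]
        except KeyError:
            warnings.warn(
                f"gene {gene_id!r}: some sites absent from the count matrix, "
                "row left missing",
                stacklevel=2,
            )
            continue
        sub = mat[rows, :]
        total = sub.sum(axis=0)
        distal = sub[-1, :]
        ok = total >= min_total
        values[gi, ok] = distal[ok] / total[ok]

    return PhiMatrix(values, gene_ids, list(counts.cell_ids))
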