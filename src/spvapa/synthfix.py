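"""Synthetic paired expression / APA data with known ground truth.

The generator emulates the statistical shape of 3'-tag single-cell data as
seen from the APA layer: K cell types; per-gene negative-binomial expression
(a subset of genes carries type-dependent fold changes — the share of class
signal in the expression modality); for every gene a two-site 3' UTR whose
per-type mean distal usage is beta-distributed, with a designated set of
planted DEAPA genes shifted by ``delta_phi`` between types; per-cell true
phi drawn from a beta around the type mean; site reads split binomially so
that RUD computed from the site counts is unbiased for the true phi; and
dropout that is *count-dependent* (low-depth entries vanish first, plus an
MCAR floor) so that the phi matrix ends up much sparser than G and its
missingness is predictable from expression — the structure the WNN
imputation exploits.

A spatial variant lays the same cells on a square grid with class labels in
contiguous bands, mimicking layered tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .apa_matrix import ExprMatrix, PhiMatrix, SiteAnnotation, SiteCounts, compute_phi, filter_apa_genes


@dataclass
class SimConfig:
    """Generation parameters; defaults define the reference study conditions."""

    n_cells: int = 300
    n_genes: int = 2000                      # expression genes (G rows)
    n_apa_genes: int = 500                   # genes with a 2-site 3' UTR (phi rows)
    n_classes: int = 3
    proportions: list[float] | None = None   # default: equal
    n_planted: int = 20                      # planted DEAPA genes
    delta_phi: float = 0.3                   # phi gap of planted genes between types
    concentration: float = 30.0              # beta precision of per-cell phi
    apa_variable_frac: float = 0.3           # fraction of APA genes with real
                                             # type-linked phi differences
    type_concentration: float = 2.5          # beta precision of per-type means
                                             # for the variable fraction
    expr_signal_frac: float = 0.2            # genes with type-dependent expression
    expr_signal_log2_sd: float = 0.8
    depth_log_mean: float = np.log(3.0)      # lognormal gene depth
    depth_log_sd: float = 1.0
    nb_size: float = 2.0                     # NB inverse-dispersion
    dropout_rate: float = 0.6                # target phi missingness
    mcar_weight: float = 0.3                 # MCAR share of the extra dropout
    spatial: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if self.proportions is None:
            self.proportions = [1.0 / self.n_classes] * self.n_classes
        if len(self.proportions) != self.n_classes:
            raise ValueError("proportions length must equal n_classes")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ValueError("proportions must sum to 1")
        if not 0 < self.delta_phi < 1:
            raise ValueError("delta_phi must be in (0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_apa_genes > self.n_genes:
            raise ValueError("n_apa_genes cannot exceed n_genes")
        if self.n_planted > self.n_apa_genes:
            raise ValueError("n_planted cannot exceed n_apa_genes")


@dataclass
class GroundTruth:
    labels: np.ndarray                 # class per cell
    phi_true: PhiMatrix                # complete true phi before dropout
    planted: pd.DataFrame              # gene, long_class (direction of longer 3' UTR)
    type_means: pd.DataFrame           # genes x classes mean phi
    expr_signal_genes: list[str]


@dataclass
class SimResult:
    expr: ExprMatrix
    site_counts: SiteCounts
    sites: list[SiteAnnotation]
    phi: PhiMatrix                     # observed (post-dropout) phi
    truth: GroundTruth
    metadata: pd.DataFrame             # label (+ x, y when spatial)
    config: SimConfig


def _class_assignment(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = np.floor(np.asarray(config.proportions) * config.n_cells).astype(int)
    counts[0] += config.n_cells - counts.sum()
    labels = np.repeat([f"C{k}" for k in range(config.n_classes)], counts)
    return rng.permutation(labels)


def _make_sites(gene_ids: list[str]) -> list[SiteAnnotation]:
    """Two 3' UTR sites per gene, alternating strands to exercise orientation."""
    sites = []
    for i, g in enumerate(gene_ids):
        base = 1000 * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        # distal = downstream in transcription direction
        prox, dist = (base + 100, base + 500) if strand == "+" else (base + 500, base + 100)
        sites.append(SiteAnnotation(f"{g}:P", "chr1", prox, prox + 1, strand, g))
        sites.append(SiteAnnotation(f"{g}:D", "chr1", dist, dist + 1, strand, g))
    return sites


def _simulate_core(config: SimConfig, labels: np.ndarray, rng: np.random.Generator) -> SimResult:
    n, p, K = config.n_cells, config.n_genes, config.n_classes
    n_apa = config.n_apa_genes
    gene_ids = [f"g{i:04d}" for i in range(p)]
    apa_gene_ids = gene_ids[:n_apa]  # the first n_apa genes carry two 3' UTR sites
    cell_ids = [f"c{i:04d}" for i in range(n)]
    class_names = [f"C{k}" for k in range(K)]
    class_idx = np.array([class_names.index(c) for c in labels])

    # per-type mean phi: beta-distributed around a gene-level base;
    # planted DEAPA genes instead carry an explicit delta_phi gap
    half = config.delta_phi / 2.0
    mu_base = np.clip(rng.beta(2, 2, size=n_apa), 0.05, 0.95)
    mu = np.tile(mu_base[:, None], (1, K))
    tc = config.type_concentration
    n_var = int(round(config.apa_variable_frac * n_apa))
    var_idx = rng.choice(n_apa, size=n_var, replace=False)
    if n_var and np.isfinite(tc):
        mu[var_idx] = np.clip(
            rng.beta(mu_base[var_idx, None] * tc, (1 - mu_base[var_idx, None]) * tc,
                     size=(n_var, K)),
            0.02, 0.98,
        )
    planted_idx = rng.choice(n_apa, size=config.n_planted, replace=False)
    planted_rows = []
    for j, g in enumerate(planted_idx):
        long_k = j % K
        base = np.clip(mu_base[g], half + 0.02, 1 - half - 0.02)
        mu[g, :] = base - half
        mu[g, long_k] = base + half
        planted_rows.append({"gene": gene_ids[g], "long_class": class_names[long_k]})

    s = config.concentration
    mu_cell = mu[:, class_idx]                     # apa genes x cells
    phi_true_vals = rng.beta(mu_cell * s, (1 - mu_cell) * s)

    # expression: lognormal depth, type-dependent fold change on a gene subset
    lam = rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=p)
    log2fc = np.zeros((p, K))
    n_sig = int(round(config.expr_signal_frac * p))
    sig_idx = rng.choice(p, size=n_sig, replace=False)
    log2fc[sig_idx, :] = rng.normal(0, config.expr_signal_log2_sd, size=(n_sig, K))
    lam_cell = lam[:, None] * 2.0 ** log2fc[:, class_idx]
    r = config.nb_size
    G_counts = rng.negative_binomial(r, r / (r + lam_cell))

    # site reads for APA genes: gene reads split proximal/distal by true phi
    total = G_counts[:n_apa].copy()
    distal = rng.binomial(total, phi_true_vals)
    proximal = total - distal

    # dropout on site counts: count-dependent thinning + MCAR floor,
    # calibrated to hit the target phi missingness exactly
    observed = total > 0
    nat_missing = int((~observed).sum())
    target_missing = int(round(config.dropout_rate * total.size))
    n_drop = target_missing - nat_missing
    if n_drop < 0:
        raise ValueError(
            f"dropout target {config.dropout_rate:.2f} below the natural "
            f"missingness {nat_missing / total.size:.2f}"
        )
    obs_flat = np.flatnonzero(observed.ravel())
    if n_drop > 0:
        logd = np.log(total.ravel()[obs_flat].astype(float))
        depth_w = 1.0 / (1.0 + np.exp(logd - np.median(logd)))  # low depth drops first
        w = config.mcar_weight + (1 - config.mcar_weight) * depth_w
        drop = rng.choice(obs_flat, size=n_drop, replace=False, p=w / w.sum())
        rr, cc = np.unravel_index(drop, total.shape)
        distal[rr, cc] = 0
        proximal[rr, cc] = 0

    # assemble site count matrix in annotation order
    sites = _make_sites(apa_gene_ids)
    site_ids = [s_.site_id for s_ in sites]
    site_mat = np.empty((2 * n_apa, n), dtype=np.int64)
    site_mat[0::2] = proximal
    site_mat[1::2] = distal
    site_counts = SiteCounts(sparse.csr_matrix(site_mat), site_ids, cell_ids)

    phi = compute_phi(site_counts, filter_apa_genes(sites), min_total=1)

    expr = ExprMatrix(G_counts.astype(float), gene_ids, cell_ids)
    truth = GroundTruth(
        labels=labels,
        phi_true=PhiMatrix(phi_true_vals, apa_gene_ids, cell_ids,
                           np.zeros_like(phi_true_vals, dtype=bool)),
        planted=pd.DataFrame(planted_rows),
        type_means=pd.DataFrame(mu, index=apa_gene_ids, columns=class_names),
        expr_signal_genes=[gene_ids[i] for i in sorted(sig_idx)],
    )
    metadata = pd.DataFrame({"label": labels}, index=cell_ids)
    return SimResult(expr, site_counts, sites, phi, truth, metadata, config)


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate a paired (G, site counts, phi) dataset with ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    labels = _class_assignment(config, rng)
    return _simulate_core(config, labels, rng)


def simulate_spatial(config: SimConfig | None = None) -> SimResult:
    """Spatial variant: cells on a square grid, classes in contiguous bands.

    ``n_cells`` is rounded down to a perfect square; the grid's rows are
    split into ``n_classes`` horizontal bands of (near) equal height, so
    class labels form layered domains as in sectioned tissue.
    """
    config = config or SimConfig(spatial=True)
    side = int(np.floor(np.sqrt(config.n_cells)))
    if side < config.n_classes:
        raise ValueError(
            f"grid side {side} too small for {config.n_classes} class bands"
        )
    n_cells = side * side
    cfg = SimConfig(**{**config.__dict__, "n_cells": n_cells, "spatial": True,
                       "proportions": None})
    yy, xx = np.divmod(np.arange(n_cells), side)
    band = np.minimum(yy * cfg.n_classes // side, cfg.n_classes - 1)
    labels = np.array([f"C{k}" for k in band])

    rng = np.random.default_rng(cfg.seed)
    result = _simulate_core(cfg, labels, rng)
    result.metadata["x"] = xx
    result.metadata["y"] = yy
    return result
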