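"""Weighted-nearest-neighbor (WNN) iterative imputation of the phi matrix.

The RUD matrix is far sparser than the gene-expression matrix G: a cell
contributes a phi value for a gene only when that gene's 3' UTR sites caught
reads.  Missing entries are recovered by borrowing phi values from the
cell's nearest neighbors.  Neighbors are defined on a fused graph over two
modalities — a PCA embedding of normalized expression and a PCA embedding of
the (current) phi matrix — with *per-cell* modality weights learned from how
well each modality's neighborhood predicts the cell's position, following
the Seurat-v4 WNN scheme.  Because the phi embedding itself depends on the
imputed values, imputation is iterated to a fixed point: fill, embed,
re-weight, re-impute, until the largest change over imputed entries drops
below ``tol``.

Gene expression has no missing entries to update, so its embedding is
computed once and held fixed across iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .apa_matrix import ExprMatrix, PhiMatrix

logger = logging.getLogger(__name__)

#: neighbors used for within/cross-modality prediction when learning weights
N_PREDICT_NEIGHBORS = 20
_EPS = 1e-12


@dataclass
class ModalityEmbedding:
    """Low-dimensional (PCA) representation of one modality."""

    coords: np.ndarray  # cells x d
    modality: str       # "expression" or "apa"

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class WNNGraph:
    """Fused k-nearest-neighbor graph with per-cell modality weights."""

    neighbors: np.ndarray   # cells x k, int indices; self excluded
    kernel_sims: np.ndarray  # cells x k, similarity in (0, 1]
    weights: np.ndarray     # cells x 2: (w_expr, w_apa), rows sum to 1

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]


@dataclass
class ImputationResult:
    phi_plus: PhiMatrix
    n_iters: int
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_mean_filled: int = 0          # entries never reachable via neighbors
    dropped_genes: list[str] = field(default_factory=list)
    graph: WNNGraph | None = None
    shrinkage: float = 1.0          # fitted attenuation of imputed deviations


def normalize_expression(G: ExprMatrix) -> np.ndarray:
    """Library-size normalize, log-transform and gene-standardize G.

    Counts of each cell are scaled to the median library size, log1p
    transformed, then each gene is centered and scaled to unit variance
    (constant genes are left at zero).  Returns a cells x genes array ready
    for PCA.
    """
    counts = G.counts
    depth = counts.sum(axis=0)
    if np.any(depth == 0):
        bad = [G.cell_ids[i] for i in np.flatnonzero(depth == 0)]
        raise ValueError(f"cells with zero total counts: {bad}")
    scaled = counts * (np.median(depth) / depth)[None, :]
    X = np.log1p(scaled).T  # cells x genes
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def initial_fill(phi: PhiMatrix) -> tuple[np.ndarray, PhiMatrix]:
    """Replace missing entries with gene-wise observed means.

    Genes with no observed value at all cannot be initialised (or ever
    imputed from data) and are dropped with a warning.  Returns the filled
    genes x cells array together with the (possibly row-subset) phi matrix
    it corresponds to.
    """
    n_obs = (~phi.mask).sum(axis=1)
    keep = n_obs > 0
    if not keep.all():
        dropped = [g for g, k in zip(phi.gene_ids, keep) if not k]
        warnings.warn(
            f"{len(dropped)} gene(s) with no observed phi dropped: "
            f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}",
            stacklevel=2,
        )
        phi = PhiMatrix(
            phi.values[keep], [g for g, k in zip(phi.gene_ids, keep) if k],
            list(phi.cell_ids), phi.mask[keep],
        )
    gene_means = np.nanmean(phi.values, axis=1)
    filled = np.where(phi.mask, gene_means[:, None], phi.values)
    return filled, phi


def embed(X: np.ndarray, d: int, modality: str = "expression") -> ModalityEmbedding:
    """Top-d PCA scores of a complete cells x features matrix.

    Uses a full (deterministic) SVD and fixes each component's sign so that
    its largest-magnitude loading is positive, making embeddings reproducible
    across runs and platforms.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("embedding input must be complete (no NaN)")
    max_d = min(X.shape) - 1
    if d > max_d:
        warnings.warn(f"d={d} exceeds usable rank; truncated to {max_d}", stacklevel=2)
        d = max_d
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest |loading| positive per component
    flip = np.sign(
        pca.components_[np.arange(d), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return ModalityEmbedding(scores * flip[None, :], modality)


def _knn(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbors per row, self excluded; ties broken by index."""
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return order, np.take_along_axis(d, order, axis=1)


#: widening factor applied to the per-cell bandwidth when turning fused
#: similarities into averaging weights: a sharply decaying kernel would
#: concentrate the neighbor average on one or two cells and defeat the
#: pooling the imputation needs, so weights within the neighbor set are
#: kept nearly flat
_SIM_BAND_WIDEN = 4.0


def modality_weights(
    e_expr: ModalityEmbedding,
    e_apa: ModalityEmbedding,
    k: int,
    w_expr_fixed: float | None = None,
) -> WNNGraph:
    """Learn per-cell modality weights and build the fused kNN graph.

    For each modality, a cell's embedding is predicted by averaging its
    ``N_PREDICT_NEIGHBORS`` nearest neighbors taken (a) within the same
    modality and (b) from the other modality.  The gap between cross- and
    within-modality prediction errors, measured on the scale of the cell's
    local neighborhood band (k-th minus 1st neighbor distance), says how
    much extra structure the modality carries; a softmax over the two gaps
    yields weights (w_expr, w_apa) summing to 1.  The fused similarity of
    cell i to j is the weighted sum of per-modality exponential kernels
    with the same per-cell bandwidth; the k most similar cells form the
    neighbor set, with near-flat kernel weights inside it.

    ``w_expr_fixed`` bypasses the learned weights (e.g. 1.0 anchors the
    graph entirely on expression).
    """
    if e_expr.n_cells != e_apa.n_cells:
        raise ValueError("embeddings cover different cell sets")
    n = e_expr.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")

    coords = {"expr": e_expr.coords, "apa": e_apa.coords}
    dist = {m: cdist(c, c) for m, c in coords.items()}
    k_pred = min(N_PREDICT_NEIGHBORS, n - 1)
    nn_idx, d1, band = {}, {}, {}
    for m in ("expr", "apa"):
        idx, nnd = _knn(dist[m], k_pred)
        nn_idx[m] = idx
        d1[m] = nnd[:, 0]
        band[m] = np.maximum(nnd[:, -1] - nnd[:, 0], _EPS)

    if w_expr_fixed is not None:
        w_expr = np.full(n, float(w_expr_fixed))
    else:
        # prediction errors: within uses own-modality neighbors, cross the other's
        score = {}
        for m, other in (("expr", "apa"), ("apa", "expr")):
            pred_within = coords[m][nn_idx[m]].mean(axis=1)
            pred_cross = coords[m][nn_idx[other]].mean(axis=1)
            d_within = np.linalg.norm(coords[m] - pred_within, axis=1)
            d_cross = np.linalg.norm(coords[m] - pred_cross, axis=1)
            score[m] = np.clip((d_cross - d_within) / band[m], -20.0, 20.0)
        ex = np.exp(score["expr"])
        ap = np.exp(score["apa"])
        w_expr = ex / (ex + ap)
    weights = np.column_stack([w_expr, 1.0 - w_expr])

    kernel = {
        m: np.exp(-np.maximum(dist[m] - d1[m][:, None], 0.0) / band[m][:, None])
        for m in ("expr", "apa")
    }
    fused = w_expr[:, None] * kernel["expr"] + (1.0 - w_expr)[:, None] * kernel["apa"]
    np.fill_diagonal(fused, -np.inf)
    order = np.argsort(-fused, axis=1, kind="stable")[:, :k]
    # averaging weights: same fused kernel, widened bandwidth (near-flat)
    picked = np.clip(np.take_along_axis(fused, order, axis=1), _EPS, 1.0)
    sims = picked ** (1.0 / _SIM_BAND_WIDEN)
    return WNNGraph(order, sims, weights)


def impute_pass(phi: PhiMatrix, graph: WNNGraph) -> PhiMatrix:
    """One sweep: fill each missing entry from observed neighbor values.

    A missing phi(g, c) becomes the kernel-similarity-weighted average of
    phi(g, j) over neighbors j of c where the gene is observed; if no
    neighbor observes the gene the entry stays missing this pass.  Observed
    entries are never touched.
    """
    if graph.n_cells != phi.n_cells:
        raise ValueError("graph and phi cover different cell sets")
    n = phi.n_cells
    W = np.zeros((n, n))
    np.put_along_axis(W, graph.neighbors, graph.kernel_sims, axis=1)

    obs = ~phi.mask
    vals = np.where(obs, phi.values, 0.0)
    num = vals @ W.T            # genes x cells
    den = obs.astype(float) @ W.T
    can = phi.mask & (den > 0)

    new_vals = phi.values.copy()
    new_vals[can] = num[can] / den[can]
    new_mask = phi.mask & ~can
    return PhiMatrix(new_vals, list(phi.gene_ids), list(phi.cell_ids), new_mask)


def _smooth_pass(current: np.ndarray, update_mask: np.ndarray, graph: WNNGraph) -> np.ndarray:
    """Replace entries under ``update_mask`` by their kernel-weighted neighbor
    average over the *complete* current matrix; other entries are untouched."""
    n = current.shape[1]
    W = np.zeros((n, n))
    np.put_along_axis(W, graph.neighbors, graph.kernel_sims, axis=1)
    den = W.sum(axis=1)
    out = current
    # iterate to the harmonic fixed point for this graph (observed pinned);
    # convex averaging keeps every value inside the gene's current range
    for _ in range(50):
        smoothed = np.clip((out @ W.T) / den[None, :], 0.0, 1.0)
        new = np.where(update_mask, smoothed, out)
        delta = float(np.max(np.abs(new - out), initial=0.0))
        out = new
        if delta < 1e-4:
            break
    return out


def iterate_impute(
    phi: PhiMatrix,
    G: ExprMatrix,
    k: int = 20,
    d: int = 30,
    max_iter: int = 10,
    tol: float = 1e-3,
    calibrate: bool = True,
    calib_frac: float = 0.1,
    seed: int = 1,
) -> ImputationResult:
    """Iteratively impute phi on a WNN graph fusing expression and APA.

    The expression embedding is computed once from G.  Each iteration embeds
    the current (filled) phi matrix, recomputes per-cell modality weights
    and the fused neighbor graph, and re-imputes every originally-missing
    entry.  The first sweep anchors the graph on expression alone (before
    any imputation the phi modality reflects only the gene-mean fill, not
    biology) and averages observed neighbor values; later sweeps use learned
    dual-modality weights and let previously imputed values propagate with
    the observed entries pinned (harmonic smoothing), so information pools
    across the whole graph rather than a cell's immediate observed
    neighbors.  Iteration stops when the maximum absolute change over
    imputed entries falls below ``tol`` or after ``max_iter`` sweeps (the
    result is then flagged non-converged, not an error).

    With ``calibrate`` (default), imputed deviations from the gene means are
    finally rescaled by a coefficient fitted on an internal validation set:
    a fraction ``calib_frac`` of the observed entries is held out, the whole
    iteration is rerun on the reduced matrix, and the held-out values are
    regressed (through the origin, as deviations from gene means) on their
    imputed estimates.  The fitted slope is the attenuation the data
    actually support — it shrinks imputed values toward the gene mean
    exactly as much as neighbor information is noisy, and approaches 1 when
    neighbors predict held-out values faithfully.  Entries that no neighbor
    ever observes are gene-mean filled so downstream steps get a complete
    matrix.
    """
    if list(phi.cell_ids) != list(G.cell_ids):
        raise ValueError("phi and G must share an identical ordered cell set")
    if min(k, d, max_iter) < 1 or tol < 0:
        raise ValueError("k, d, max_iter must be positive and tol >= 0")

    if not phi.mask.any():
        return ImputationResult(phi_plus=phi.copy(), n_iters=0)

    X_expr = normalize_expression(G)
    d_expr = min(d, min(X_expr.shape) - 1)
    e_expr = embed(X_expr, d_expr, "expression")

    shrinkage = 1.0
    if calibrate:
        shrinkage = _holdout_shrinkage(
            phi, e_expr, k=k, d=d, max_iter=max_iter, tol=tol,
            frac=calib_frac, seed=seed,
        )

    core = _iterate_core(phi, e_expr, k=k, d=d, max_iter=max_iter, tol=tol)
    current = core["current"]
    gene_means = core["gene_means"]
    if shrinkage < 1.0:
        dev = current - gene_means[:, None]
        current = np.where(
            core["orig_mask"],
            np.clip(gene_means[:, None] + shrinkage * dev, 0.0, 1.0),
            current,
        )
    logger.info("imputation shrinkage coefficient: %.3f", shrinkage)

    phi_kept = core["phi_kept"]
    phi_plus = PhiMatrix(
        current, list(phi_kept.gene_ids), list(phi_kept.cell_ids),
        np.zeros_like(core["orig_mask"]),
    )
    return ImputationResult(
        phi_plus=phi_plus,
        n_iters=core["n_iters"],
        trace=core["trace"],
        converged=core["converged"],
        n_mean_filled=core["n_mean_filled"],
        dropped_genes=[g for g in phi.gene_ids if g not in set(phi_kept.gene_ids)],
        graph=core["graph"],
        shrinkage=shrinkage,
    )


def _iterate_core(
    phi: PhiMatrix,
    e_expr: ModalityEmbedding,
    k: int,
    d: int,
    max_iter: int,
    tol: float,
) -> dict:
    """The embed / re-weight / impute loop; returns the unshrunk fill."""
    filled, phi_kept = initial_fill(phi)
    orig_mask = phi_kept.mask
    gene_means = np.nanmean(phi_kept.values, axis=1)

    trace: list[float] = []
    converged = False
    graph = None
    never_imputed = orig_mask.copy()
    current = filled
    n_iters = 0

    for n_iters in range(1, max_iter + 1):
        # phi modality: per-gene centering only (phi already bounded)
        X_apa = (current - current.mean(axis=1, keepdims=True)).T
        d_apa = min(d, min(X_apa.shape) - 1)
        e_apa = embed(X_apa, d_apa, "apa")
        graph = modality_weights(
            e_expr, e_apa, k, w_expr_fixed=1.0 if n_iters == 1 else None
        )

        if n_iters == 1:
            # first sweep: observed neighbor values only
            result = impute_pass(phi_kept, graph)
            never_imputed &= result.mask
            new_filled = np.where(result.mask, gene_means[:, None], result.values)
        else:
            # later sweeps: previously imputed values also propagate, with the
            # observed entries pinned — harmonic smoothing on the WNN graph.
            # This pools information across the whole graph instead of only a
            # cell's immediate observed neighbors, which is what lets the
            # iteration denoise beyond a single kNN average.
            new_filled = _smooth_pass(current, orig_mask, graph)

        max_change = float(np.max(np.abs(new_filled - current)[orig_mask], initial=0.0))
        trace.append(max_change)
        logger.info("imputation iteration %d: max change %.6f", n_iters, max_change)
        current = new_filled
        if max_change < tol:
            converged = True
            break

    if not converged:
        logger.warning("imputation did not converge in %d iterations", max_iter)

    return {
        "current": current, "phi_kept": phi_kept, "orig_mask": orig_mask,
        "gene_means": gene_means, "trace": trace, "converged": converged,
        "n_iters": n_iters, "n_mean_filled": int(never_imputed.sum()),
        "graph": graph,
    }


def _holdout_shrinkage(
    phi: PhiMatrix,
    e_expr: ModalityEmbedding,
    k: int,
    d: int,
    max_iter: int,
    tol: float,
    frac: float,
    seed: int,
) -> float:
    """Fit the attenuation of imputed deviations on held-out observed entries.

    A random ``frac`` of the observed entries is additionally masked, the
    iteration is rerun, and the held-out values are regressed through the
    origin on their imputed estimates (both as deviations from the reduced
    matrix's gene means).  The slope is < 1 exactly when neighbor averages
    over-state how much they know.
    """
    rng = np.random.default_rng(seed)
    obs_r, obs_c = np.nonzero(~phi.mask)
    n_hold = int(np.floor(frac * obs_r.size))
    if n_hold < 50:  # too few entries for a stable fit
        return 1.0
    pick = rng.choice(obs_r.size, size=n_hold, replace=False)
    hr, hc = obs_r[pick], obs_c[pick]
    mask2 = phi.mask.copy()
    mask2[hr, hc] = True
    phi2 = PhiMatrix(
        np.where(mask2, np.nan, phi.values),
        list(phi.gene_ids), list(phi.cell_ids), mask2,
    )
    core = _iterate_core(phi2, e_expr, k=k, d=d, max_iter=max_iter, tol=tol)
    kept_index = {g: i for i, g in enumerate(core["phi_kept"].gene_ids)}
    gm = core["gene_means"]
    est, act = [], []
    for r, c in zip(hr, hc):
        i = kept_index.get(phi.gene_ids[r])
        if i is None:
            continue
        est.append(core["current"][i, c] - gm[i])
        act.append(phi.values[r, c] - gm[i])
    est = np.asarray(est)
    act = np.asarray(act)
    denom = float(est @ est)
    if denom < _EPS:
        return 1.0
    return float(np.clip((act @ est) / denom, 0.0, 1.0))


def gene_mean_fill(phi: PhiMatrix) -> PhiMatrix:
    """Baseline imputation: every missing entry gets its gene's observed mean."""
    filled, phi_kept = initial_fill(phi)
    return PhiMatrix(
        filled, list(phi_kept.gene_ids), list(phi_kept.cell_ids),
        np.zeros_like(phi_kept.mask),
    )
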