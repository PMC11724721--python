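"""Low-dimensional visualization integrating the APA and expression modalities.

Three regimes are supported, selected by a ``scheme`` name:

* unsupervised — PCA then UMAP of a single (complete) matrix;
* semisupervised — ``spls+umap``: sPLS-DA is fitted separately on the
  expression and imputed-phi modalities, the two score matrices are
  column-standardized and concatenated, and UMAP embeds the concatenation.
  Labels shape the latent space; UMAP still discovers local structure.
* supervised — ``spls-only``: the first two sPLS-DA components directly.

All embeddings are deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .apa_matrix import ExprMatrix, PhiMatrix
from .feature_select import fit_splsda
from .wnn_impute import normalize_expression

SCHEMES = ("pca+umap", "spls+umap", "pls+umap", "spls-only")


@dataclass
class EmbeddingResult:
    coords: np.ndarray          # cells x 2
    source: str
    cell_ids: list[str]
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.cell_ids, columns=["dim1", "dim2"])


def _umap_embed(X: np.ndarray, seed: int, n_neighbors: int = 30, min_dist: float = 0.3):
    import umap  # deferred: numba compilation is slow at import time

    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        return np.asarray(reducer.fit_transform(X), dtype=float)


def umap_unsupervised(
    phi_plus: PhiMatrix,
    d: int = 30,
    seed: int = 1,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
) -> EmbeddingResult:
    """PCA to ``d`` dimensions then UMAP to 2, on a complete phi matrix."""
    if phi_plus.n_cells < 10:
        raise ValueError("need at least 10 cells for a meaningful embedding")
    if phi_plus.mask.any():
        raise ValueError("phi matrix has missing entries; impute first")
    X = phi_plus.values.T  # cells x genes
    d = min(d, min(X.shape) - 1)
    pcs = PCA(n_components=d, svd_solver="full").fit_transform(X - X.mean(axis=0))
    coords = _umap_embed(pcs, seed, n_neighbors, min_dist)
    return EmbeddingResult(
        coords, "pca+umap", list(phi_plus.cell_ids),
        {"d": d, "seed": seed, "n_neighbors": n_neighbors, "min_dist": min_dist},
    )


def _modality_scores(X: np.ndarray, y, n_comp: int, keepX: int | None) -> np.ndarray:
    kx = X.shape[1] if keepX is None else min(keepX, X.shape[1])
    model = fit_splsda(X, y, n_comp=n_comp, keepX=kx)
    return model.scores


def spls_umap(
    G: ExprMatrix,
    phi_plus: PhiMatrix,
    labels,
    n_comp: int = 2,
    keepX: int | None = 50,
    seed: int = 1,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
    use_umap: bool = True,
) -> EmbeddingResult:
    """Semisupervised dual-modality embedding (sPLS + UMAP).

    sPLS-DA is fitted separately on normalized expression and on the imputed
    phi matrix; the two score matrices are standardized per column (so
    neither modality dominates by scale), concatenated, and embedded by
    UMAP.  With ``keepX=None`` the dense fit gives the plain PLS-DA variant;
    with ``use_umap=False`` the first two concatenated components are
    returned directly.
    """
    if list(G.cell_ids) != list(phi_plus.cell_ids):
        only_g = set(G.cell_ids) - set(phi_plus.cell_ids)
        only_p = set(phi_plus.cell_ids) - set(G.cell_ids)
        raise ValueError(
            f"modalities cover different cells (expression-only: {sorted(only_g)[:5]}, "
            f"apa-only: {sorted(only_p)[:5]}) or different orderings"
        )
    if phi_plus.mask.any():
        raise ValueError("phi matrix has missing entries; impute first")

    S_expr = _modality_scores(normalize_expression(G), labels, n_comp, keepX)
    S_apa = _modality_scores(phi_plus.values.T, labels, n_comp, keepX)

    def _standardize(S: np.ndarray) -> np.ndarray:
        sd = S.std(axis=0)
        sd[sd == 0] = 1.0
        return (S - S.mean(axis=0)) / sd

    fused = np.hstack([_standardize(S_expr), _standardize(S_apa)])
    if use_umap:
        coords = _umap_embed(fused, seed, n_neighbors, min_dist)
        source = "spls+umap" if keepX is not None else "pls+umap"
    else:
        coords = fused[:, :2]
        source = "spls-only"
    return EmbeddingResult(
        coords, source, list(phi_plus.cell_ids),
        {"n_comp": n_comp, "keepX": keepX, "seed": seed},
    )


def run_scheme(
    scheme: str,
    phi_plus: PhiMatrix,
    G: ExprMatrix | None = None,
    labels=None,
    seed: int = 1,
    **kwargs,
) -> EmbeddingResult:
    """Dispatch on the visualization scheme name (see ``SCHEMES``)."""
    if scheme == "pca+umap":
        return umap_unsupervised(phi_plus, seed=seed, **kwargs)
    if scheme in {"spls+umap", "pls+umap", "spls-only"}:
        if G is None or labels is None:
            raise ValueError(f"scheme {scheme!r} needs both modalities and labels")
        if scheme == "pls+umap":
            kwargs["keepX"] = None
        return spls_umap(
            G, phi_plus, labels, seed=seed,
            use_umap=(scheme != "spls-only"), **kwargs,
        )
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def embedding_plot(
    result: EmbeddingResult, labels, out_path: str, title: str | None = None
) -> None:
    """Scatter an embedding colored by class label."""
    yarr = np.asarray(labels).astype(str)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for c in np.unique(yarr):
        m = yarr == c
        ax.scatter(result.coords[m, 0], result.coords[m, 1], s=8, label=c, alpha=0.8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(markerscale=2, fontsize=8)
    ax.set_title(title or result.source)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def spatial_map(
    values,
    coords: pd.DataFrame,
    out_path: str,
    phi_scale: bool = True,
    cmap: str = "viridis",
) -> None:
    """Map per-spot values onto array coordinates, one panel per row.

    ``values`` is a Series (one map) or a DataFrame (one panel per row, e.g.
    the meta-phi matrix).  With ``phi_scale`` the color range is fixed to
    [0, 1]; values outside it trigger a warning and autoscaling.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame().T
    if not {"x", "y"}.issubset(coords.columns):
        raise ValueError("coords must provide 'x' and 'y' columns")
    missing = [c for c in values.columns if c not in coords.index]
    if missing:
        raise ValueError(f"spots without coordinates: {missing[:5]}")
    xy = coords.loc[values.columns, ["x", "y"]].to_numpy(dtype=float)

    n_panels = values.shape[0]
    fig, axes = plt.subplots(
        1, n_panels, figsize=(3.2 * n_panels, 3.0), squeeze=False
    )
    for ax, (name, row) in zip(axes[0], values.iterrows()):
        v = row.to_numpy(dtype=float)
        vmin, vmax = (0.0, 1.0) if phi_scale else (None, None)
        if phi_scale and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            warnings.warn(
                f"panel {name!r}: values outside [0, 1]; autoscaling color range",
                stacklevel=2,
            )
            vmin = vmax = None
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=v, s=14, cmap=cmap, vmin=vmin, vmax=vmax)
        ax.set_title(str(name), fontsize=9)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
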