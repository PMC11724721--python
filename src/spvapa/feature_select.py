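"""Supervised APA feature selection by sparse PLS-DA.

phi values are bounded ratios, not counts, so count-based differential
models do not apply.  Sparse partial least squares discriminant analysis
(sPLS-DA) instead finds latent components — linear combinations of a small
number of genes (``keepX`` per component) — that maximally covary with a
one-hot encoding of the cell labels.  Each component acts as a "meta-gene";
its nonzero loadings name the APA features driving one axis of between-class
variation.  Tuning selects keepX per component (and the number of
components) by stratified cross-validated balanced error rate.

The fit is NIPALS-style: per component, alternate
``loading <- soft-threshold(X^T u)`` (keeping the top-keepX entries by
magnitude) with the Y-side update until convergence, then deflate X and Y by
regression on the component score.  Scores of successive components are
therefore orthogonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .apa_matrix import PhiMatrix

_TOL = 1e-9
_MAX_NIPALS = 500


@dataclass
class SPLSDAModel:
    """Fitted sparse PLS-DA model.

    ``loadings`` columns are unit-norm with exactly ``keepX[h]`` nonzeros;
    ``scores = X_centered @ rotation`` (deflation-adjusted);
    ``class_loadings[k, h]`` is the regression coefficient of class k's
    one-hot indicator on component h.
    """

    n_comp: int
    loadings: np.ndarray        # p x H, sparse unit-norm weight vectors
    x_reg_loadings: np.ndarray  # p x H, deflation regression loadings
    scores: np.ndarray          # n x H
    class_loadings: np.ndarray  # K x H
    keepX: list[int]
    selected: list[list[str]]   # per component, gene ids with nonzero loading
    classes: list[str]
    gene_ids: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """W (P^T W)^{-1}: maps centered X directly to scores."""
        A, P = self.loadings, self.x_reg_loadings
        return A @ np.linalg.inv(P.T @ A)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) @ self.rotation

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Max-distance rule: argmax of the predicted one-hot response."""
        y_hat = self.transform(X) @ self.class_loadings.T + self.y_mean
        return np.asarray(self.classes)[np.argmax(y_hat, axis=1)]


@dataclass
class CVResult:
    grid: pd.DataFrame            # columns: comp, keepX, error
    chosen_keepX: list[int]
    n_comp: int
    errors: list[float]           # CV balanced error per retained component
    folds: int
    model: SPLSDAModel | None = None
    fold_assignment: np.ndarray | None = None


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, list[str]]:
    classes = sorted(pd.unique(pd.Series(y).astype(str)))
    Y = np.zeros((len(y), len(classes)))
    for k, c in enumerate(classes):
        Y[np.asarray(y).astype(str) == c, k] = 1.0
    return Y, classes


def _sparse_loading(a: np.ndarray, keep: int) -> np.ndarray:
    """Keep the top-``keep`` entries of |a|, soft-threshold the rest to zero.

    The threshold is the (keep+1)-th largest magnitude; ties at the boundary
    are resolved by ascending index so the nonzero count is exactly ``keep``.
    """
    p = a.size
    if keep >= p:
        return a.copy()
    order = np.argsort(-np.abs(a), kind="stable")
    lam = np.abs(a[order[keep]])
    out = np.zeros_like(a)
    kept = order[:keep]
    shrunk = np.abs(a[kept]) - lam
    if np.all(shrunk <= 1e-12 * max(lam, _TOL)):
        # every kept entry (near-)ties the threshold: hard-select, no shrink
        out[kept] = a[kept]
        return out
    shrunk[shrunk <= 0] = _TOL  # partial ties at the boundary: keep count exact
    out[kept] = np.sign(a[kept]) * shrunk
    return out


def fit_splsda(
    X: np.ndarray,
    y,
    n_comp: int,
    keepX: int | list[int],
    gene_ids: list[str] | None = None,
) -> SPLSDAModel:
    """Fit sparse PLS-DA of a complete cells x genes matrix on class labels.

    Parameters
    ----------
    X
        Complete (no NaN) cells x genes matrix, e.g. imputed phi values;
        columns are centered internally, not variance-scaled.
    y
        Per-cell class labels (K >= 2 classes).
    n_comp
        Number of latent components H; must satisfy H < min(n, p).
    keepX
        Number of genes retained per component (scalar or list of length H).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X must be complete; impute phi first")
    n, p = X.shape
    if n_comp < 1 or n_comp >= min(n, p):
        raise ValueError(f"n_comp must be in [1, min(n, p) - 1] = [1, {min(n, p) - 1}]")
    keepX = [keepX] * n_comp if np.isscalar(keepX) else list(keepX)
    if len(keepX) != n_comp:
        raise ValueError("keepX list length must equal n_comp")
    if any(kx < 1 or kx > p for kx in keepX):
        raise ValueError(f"each keepX must be in [1, p={p}]")
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(p)]

    yarr = np.asarray(y)
    if len(yarr) != n:
        raise ValueError("y length must match number of rows of X")
    Y, classes = _one_hot(yarr)
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    H, K = n_comp, len(classes)
    A = np.zeros((p, H))
    P = np.zeros((p, H))
    T = np.zeros((n, H))
    D = np.zeros((K, H))
    selected: list[list[str]] = []

    Xd, Yd = Xc.copy(), Yc.copy()
    for h in range(H):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if np.linalg.norm(u) < _TOL:
            u = Yd[:, 0] + _TOL
        a = None
        for _ in range(_MAX_NIPALS):
            a = _sparse_loading(Xd.T @ u, keepX[h])
            nrm = np.linalg.norm(a)
            if nrm < _TOL:
                raise ValueError(f"component {h + 1}: degenerate (zero) loading")
            a /= nrm
            t = Xd @ a
            b = Yd.T @ t / (t @ t)
            bn = np.linalg.norm(b)
            if bn < _TOL:
                break
            u_new = Yd @ (b / bn)
            if np.linalg.norm(u_new - u) < 1e-8 * max(np.linalg.norm(u_new), 1.0):
                u = u_new
                break
            u = u_new
        t = Xd @ a
        tt = t @ t
        if tt < _TOL:
            raise ValueError(f"component {h + 1}: zero-variance score")
        ph = Xd.T @ t / tt
        dh = Yd.T @ t / tt
        # reproducible sign: largest-|loading| entry positive
        j = int(np.argmax(np.abs(a)))
        if a[j] < 0:
            a, t, ph, dh = -a, -t, -ph, -dh
        A[:, h], P[:, h], T[:, h], D[:, h] = a, ph, t, dh
        selected.append([gene_ids[j] for j in np.flatnonzero(a)])
        Xd = Xd - np.outer(t, ph)
        Yd = Yd - np.outer(t, dh)

    return SPLSDAModel(
        n_comp=H, loadings=A, x_reg_loadings=P, scores=T, class_loadings=D,
        keepX=keepX, selected=selected, classes=classes, gene_ids=list(gene_ids),
        x_mean=x_mean, y_mean=y_mean,
    )


def balanced_error_rate(y_true, y_pred) -> float:
    """1 - mean per-class recall (chance level: 1 - 1/K)."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)
    ]
    return float(1.0 - np.mean(recalls))


def tune(
    X: np.ndarray,
    y,
    keepX_grid: list[int] | None = None,
    max_comp: int | None = None,
    folds: int = 10,
    seed: int = 1,
    gene_ids: list[str] | None = None,
    improve_tol: float = 0.01,
) -> CVResult:
    """Sequentially tune keepX per component by stratified k-fold CV.

    Components are added one at a time: with earlier components' keepX
    fixed, every grid value is scored by mean balanced error rate over the
    folds (max-distance prediction); the best (ties -> smaller keepX) is
    kept.  A new component is retained only while it improves the error by
    more than ``improve_tol`` — otherwise tuning stops (parsimony).  The
    returned model is refit on all cells with the chosen configuration.
    """
    X = np.asarray(X, dtype=float)
    yarr = np.asarray(y).astype(str)
    n, p = X.shape
    if keepX_grid is None:
        keepX_grid = [5, 10, 20, 30, 50, 100, 200, 300]
    keepX_grid = sorted({kx for kx in keepX_grid if kx <= p})
    if not keepX_grid:
        raise ValueError("keepX grid has no value <= number of genes")

    classes, counts = np.unique(yarr, return_counts=True)
    K = len(classes)
    if max_comp is None:
        max_comp = K + 1
    max_comp = min(max_comp, min(n, p) - 1)
    smallest = int(counts.min())
    if folds > smallest:
        warnings.warn(
            f"smallest class has {smallest} cells < {folds} folds; "
            f"using {max(2, smallest)} folds",
            stacklevel=2,
        )
        folds = max(2, smallest)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, yarr))
    fold_assignment = np.zeros(n, dtype=int)
    for f, (_, val) in enumerate(splits):
        fold_assignment[val] = f

    rows = []
    chosen: list[int] = []
    errors: list[float] = []
    prev_err = 1.0 - counts.max() / n  # error of majority-class guessing
    for h in range(1, max_comp + 1):
        best_err, best_kx = np.inf, None
        for kx in keepX_grid:
            fold_errs = []
            for train, val in splits:
                model = fit_splsda(
                    X[train], yarr[train], n_comp=h, keepX=chosen + [kx],
                    gene_ids=gene_ids,
                )
                fold_errs.append(balanced_error_rate(yarr[val], model.predict(X[val])))
            err = float(np.mean(fold_errs))
            rows.append({"comp": h, "keepX": kx, "error": err})
            if err < best_err - 1e-12:  # ascending grid: ties keep smaller keepX
                best_err, best_kx = err, kx
        if chosen and best_err > prev_err - improve_tol:
            break
        chosen.append(best_kx)
        errors.append(best_err)
        prev_err = best_err

    model = fit_splsda(X, yarr, n_comp=len(chosen), keepX=chosen, gene_ids=gene_ids)
    return CVResult(
        grid=pd.DataFrame(rows), chosen_keepX=chosen, n_comp=len(chosen),
        errors=errors, folds=folds, model=model, fold_assignment=fold_assignment,
    )


def component_class_map(model: SPLSDAModel, y) -> list[dict]:
    """Annotate each component with the class whose score median is extreme.

    Scores are centered overall, so the class with the largest |median| is
    the one the component singles out (in either direction — the annotation
    is invariant to a global sign flip of the component).  Components whose
    class medians are all (near) equal are annotated ``"none"`` and flagged.
    """
    yarr = np.asarray(y).astype(str)
    out = []
    for h in range(model.n_comp):
        s = model.scores[:, h]
        medians = {c: float(np.median(s[yarr == c])) for c in model.classes}
        vals = np.array(list(medians.values()))
        spread = vals.max() - vals.min()
        if spread < 1e-8 * max(float(np.abs(s).max()), 1.0):
            out.append({"component": h + 1, "class": "none", "degenerate": True,
                        "medians": medians})
            continue
        best = max(medians, key=lambda c: abs(medians[c]))
        out.append({"component": h + 1, "class": best, "degenerate": False,
                    "medians": medians})
    return out


def meta_phi(model: SPLSDAModel, phi_plus: PhiMatrix) -> pd.DataFrame:
    """Per-component mean phi over the component's selected genes.

    meta-phi(h, c) averages the imputed RUD of component h's selected genes
    in cell/spot c — a bounded [0, 1] summary of the meta-gene's 3' UTR
    usage, suitable for spatial mapping.
    """
    df = phi_plus.to_frame()
    rows = {}
    for h, genes in enumerate(model.selected, start=1):
        if not genes:
            raise ValueError(f"component {h} has an empty selection")
        missing = [g for g in genes if g not in df.index]
        if missing:
            raise ValueError(f"selected genes absent from phi matrix: {missing[:5]}")
        rows[f"comp{h}"] = df.loc[genes].mean(axis=0)
    return pd.DataFrame(rows).T


def nonredundant_features(model: SPLSDAModel) -> pd.DataFrame:
    """Union of selected genes over components, ranked by max |loading|."""
    best: dict[str, dict] = {}
    for h in range(model.n_comp):
        col = model.loadings[:, h]
        for j in np.flatnonzero(col):
            g = model.gene_ids[j]
            w = abs(float(col[j]))
            if g not in best or w > best[g]["weight"]:
                best[g] = {"gene": g, "weight": w, "component": h + 1,
                           "loading": float(col[j])}
    df = pd.DataFrame(list(best.values()), columns=["gene", "weight", "component", "loading"])
    return df.sort_values(["weight", "gene"], ascending=[False, True]).reset_index(drop=True)
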