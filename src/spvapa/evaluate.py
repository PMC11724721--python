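"""Evaluation protocol: profile correlation, silhouette, masking, DEAPA.

Imputation quality is judged the way the original data allow: the raw
observed phi matrix is the gold standard.  Observed entries are randomly
masked to raise the dropout rate, the masked matrix is imputed, and the
result is scored by (a) per-cell Pearson correlation with the raw
class-average APA profile, (b) silhouette separation of an embedding, and
(c) recovery of genes with differential APA usage (DEAPA): Wilcoxon
rank-sum per gene per class pair with Benjamini-Hochberg adjustment,
compared against the DEAPA calls of the unmasked matrix via precision /
recall / F1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score as _sk_silhouette
from statsmodels.stats.multitest import multipletests

from .apa_matrix import ExprMatrix, PhiMatrix

#: per-side group size up to which rank-sum p-values are computed by
#: exhaustive permutation enumeration (handles ties exactly)
_EXACT_N = 8
#: above this per-group size the normal approximation with tie correction is used
_APPROX_N = 25


def profile_pcc(phi_eval: PhiMatrix, phi_ref: PhiMatrix, labels) -> pd.Series:
    """Per-cell Pearson correlation with the raw class-average APA profile.

    The reference profile of class k is the gene-wise mean of *observed*
    phi values in ``phi_ref`` over cells of class k.  Each cell of
    ``phi_eval`` is correlated with its own class's reference over the genes
    observed in both; cells with fewer than 3 shared genes get NaN.
    """
    if list(phi_eval.cell_ids) != list(phi_ref.cell_ids):
        raise ValueError("phi matrices cover different cell sets")
    ref_df = phi_ref.to_frame()
    eval_df = phi_eval.to_frame().reindex(ref_df.index)
    yarr = np.asarray(labels).astype(str)
    if len(yarr) != phi_eval.n_cells:
        raise ValueError("labels length must match cell count")

    class_means = {}
    for c in np.unique(yarr):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gene rows
            class_means[c] = np.nanmean(ref_df.values[:, yarr == c], axis=1)

    out = np.full(phi_eval.n_cells, np.nan)
    ev = eval_df.values
    for i in range(phi_eval.n_cells):
        ref = class_means[yarr[i]]
        ok = ~np.isnan(ev[:, i]) & ~np.isnan(ref)
        if ok.sum() < 3:
            continue
        a, b = ev[ok, i], ref[ok]
        if a.std() == 0 or b.std() == 0:
            continue
        out[i] = np.corrcoef(a, b)[0, 1]
    return pd.Series(out, index=phi_eval.cell_ids, name="pcc")


def silhouette(X: np.ndarray, labels, n_pcs: int | None = None) -> float:
    """Mean silhouette coefficient over cells (Euclidean distance).

    ``X`` is cells x features; when ``n_pcs`` is given the score is computed
    on that many principal components (the representation used is up to the
    caller and should be reported alongside the score).  Singleton classes
    contribute 0 per the usual convention (a warning is emitted).
    """
    X = np.asarray(X, dtype=float)
    yarr = np.asarray(labels).astype(str)
    classes, counts = np.unique(yarr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("silhouette needs at least two classes")
    if (counts == 1).any():
        warnings.warn("singleton class present; its cells score 0", stacklevel=2)
    if n_pcs is not None and n_pcs < min(X.shape):
        X = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    return float(_sk_silhouette(X, yarr, metric="euclidean"))


def mask(
    phi: PhiMatrix, G: ExprMatrix | None, rate: float, seed: int = 1
) -> tuple[PhiMatrix, ExprMatrix | None, np.ndarray]:
    """Randomly mask a fraction of the observed phi entries (MCAR).

    ``floor(rate * n_observed)`` observed entries are set to missing; the
    corresponding (gene, cell) entries of G, when given, are zeroed so both
    modalities lose the same information.  Returns the masked phi, the
    masked G and the masked positions as an (m, 2) array of (row, col).
    """
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    obs_rows, obs_cols = np.nonzero(~phi.mask)
    n_mask = int(np.floor(rate * obs_rows.size))
    pick = rng.choice(obs_rows.size, size=n_mask, replace=False)
    rows, cols = obs_rows[pick], obs_cols[pick]

    new_mask = phi.mask.copy()
    new_mask[rows, cols] = True
    phi_minus = PhiMatrix(
        np.where(new_mask, np.nan, phi.values),
        list(phi.gene_ids), list(phi.cell_ids), new_mask,
    )

    G_minus = None
    if G is not None:
        counts = G.counts.copy()
        gidx = {g: i for i, g in enumerate(G.gene_ids)}
        for r, c in zip(rows, cols):
            gi = gidx.get(phi.gene_ids[r])
            if gi is not None:
                counts[gi, c] = 0
        G_minus = ExprMatrix(counts, list(G.gene_ids), list(G.cell_ids))
    return phi_minus, G_minus, np.column_stack([rows, cols])


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating every group assignment.

    Works on (mid-)ranks so ties are handled exactly.  The two-sided p-value
    is the null probability of a U statistic at least as far from its mean
    n1*n2/2 as the observed one.
    """
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * len(b) / 2
    sums = np.array([
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ])
    u_null = sums - n1 * (n1 + 1) / 2
    p = float(np.mean(np.abs(u_null - center) >= np.abs(u_obs - center) - 1e-12))
    return float(u_obs), p


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value: exact enumeration for small groups
    (ties included), normal approximation with tie correction otherwise."""
    n1, n2 = len(a), len(b)
    if max(n1, n2) <= _EXACT_N:
        return _exact_ranksum_p(a, b)
    if max(n1, n2) <= _APPROX_N and len(np.unique(np.concatenate([a, b]))) == n1 + n2:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DEAPAResult:
    """Per class-pair differential APA usage calls."""

    table: pd.DataFrame  # pair, gene, statistic, p, p_adj, significant, direction
    alpha: float
    n_untestable: dict[str, int] = field(default_factory=dict)

    def significant_genes(self, pair: str) -> set[str]:
        t = self.table
        return set(t.loc[(t["pair"] == pair) & t["significant"], "gene"])

    @property
    def pairs(self) -> list[str]:
        return sorted(self.table["pair"].unique())


def deapa(
    phi: PhiMatrix, labels, alpha: float = 0.05, min_cells: int = 2
) -> DEAPAResult:
    """Identify DEAPA genes between every pair of classes.

    For each gene and each unordered class pair, observed phi values of the
    two groups are compared by a two-sided Wilcoxon rank-sum test; p-values
    are Benjamini-Hochberg adjusted across genes within the pair, and genes
    with adjusted p < ``alpha`` are called significant.  The reported
    direction is the class with the higher median phi (higher distal usage,
    i.e. the longer 3' UTR).  Genes with fewer than ``min_cells`` observed
    values in either group are untestable and only counted.
    """
    yarr = np.asarray(labels).astype(str)
    if len(yarr) != phi.n_cells:
        raise ValueError("labels length must match cell count")
    classes = sorted(np.unique(yarr))
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    rows = []
    n_untestable: dict[str, int] = {}
    for ca, cb in itertools.combinations(classes, 2):
        pair = f"{ca}_vs_{cb}"
        ia, ib = yarr == ca, yarr == cb
        skipped = 0
        pair_rows = []
        for gi, gene in enumerate(phi.gene_ids):
            va = phi.values[gi, ia]
            vb = phi.values[gi, ib]
            va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
            if len(va) < min_cells or len(vb) < min_cells:
                skipped += 1
                continue
            stat, p = _ranksum_p(va, vb)
            med_a, med_b = np.median(va), np.median(vb)
            direction = ca if med_a > med_b else (cb if med_b > med_a else "tie")
            pair_rows.append(
                {"pair": pair, "gene": gene, "statistic": stat, "p": p,
                 "direction": direction}
            )
        n_untestable[pair] = skipped
        if pair_rows:
            pdf = pd.DataFrame(pair_rows)
            rej, p_adj, _, _ = multipletests(pdf["p"], alpha=alpha, method="fdr_bh")
            pdf["p_adj"] = p_adj
            pdf["significant"] = rej
            pdf.loc[~pdf["significant"], "direction"] = ""
            rows.append(pdf)

    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["pair", "gene", "statistic", "p", "direction", "p_adj", "significant"]
        )
    )
    return DEAPAResult(table=table, alpha=alpha, n_untestable=n_untestable)


def recovery_scores(reference: DEAPAResult, recovered: DEAPAResult) -> pd.DataFrame:
    """Precision / recall / F1 of recovered DEAPA gene sets per class pair.

    The reference sets come from the unmasked matrix; empty reference sets
    yield NaN metrics (reported, not raised).
    """
    rows = []
    for pair in reference.pairs:
        ref = reference.significant_genes(pair)
        rec = recovered.significant_genes(pair)
        tp = len(ref & rec)
        precision = tp / len(rec) if rec else np.nan
        recall = tp / len(ref) if ref else np.nan
        if not ref:
            f1 = np.nan  # undefined: nothing to recover
        elif tp == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append(
            {"pair": pair, "n_reference": len(ref), "n_recovered": len(rec),
             "tp": tp, "precision": precision, "recall": recall, "f1": f1}
        )
    return pd.DataFrame(rows)


def mask_recovery_experiment(
    phi: PhiMatrix,
    G: ExprMatrix,
    labels,
    rates=(0.3, 0.5, 0.7),
    seed: int = 1,
    alpha: float = 0.05,
    k: int = 20,
    phi_truth: PhiMatrix | None = None,
) -> pd.DataFrame:
    """Run the full masking-recovery protocol and collect its metrics.

    For each masking rate: observed entries of phi (and the matching G
    entries) are masked, the masked matrix is WNN-imputed, and three scores
    are taken — (a) DEAPA-recovery F1 against the unmasked reference, for
    both the imputed matrix and the masked matrix without imputation;
    (b) recovery PCC at the masked positions (against the true phi when a
    ground-truth matrix is supplied, else against the held-out observed
    values), for the imputation and for a gene-mean-fill baseline;
    (c) the fraction of cells whose profile correlation with the raw class
    means improves after imputation.  One row per rate.
    """
    from .wnn_impute import gene_mean_fill, iterate_impute

    yarr = np.asarray(labels).astype(str)
    reference = deapa(phi, yarr, alpha=alpha)
    rows = []
    for rate in rates:
        phi_minus, G_minus, pos = mask(phi, G, rate, seed=seed)
        rr, cc = pos[:, 0], pos[:, 1]
        imputed = iterate_impute(phi_minus, G_minus, k=k, seed=seed)
        baseline = gene_mean_fill(phi_minus)

        if phi_truth is not None:
            target = phi_truth.to_frame().reindex(phi.gene_ids).to_numpy()[rr, cc]
        else:
            target = phi.values[rr, cc]
        imp_df = imputed.phi_plus.to_frame().reindex(phi.gene_ids)
        base_df = baseline.to_frame().reindex(phi.gene_ids)
        imp_vals = imp_df.to_numpy()[rr, cc]
        base_vals = base_df.to_numpy()[rr, cc]
        ok = ~np.isnan(imp_vals) & ~np.isnan(base_vals) & ~np.isnan(target)
        pcc_wnn = float(np.corrcoef(imp_vals[ok], target[ok])[0, 1])
        pcc_base = float(np.corrcoef(base_vals[ok], target[ok])[0, 1])

        f1_wnn = float(np.nanmean(
            recovery_scores(reference, deapa(imputed.phi_plus, yarr, alpha=alpha))["f1"]
        ))
        f1_masked = float(np.nanmean(
            recovery_scores(reference, deapa(phi_minus, yarr, alpha=alpha))["f1"]
        ))

        prof_plus = profile_pcc(imputed.phi_plus, phi, yarr)
        prof_minus = profile_pcc(phi_minus, phi, yarr)
        both = prof_plus.notna() & prof_minus.notna()
        frac_improved = float((prof_plus[both] > prof_minus[both]).mean())

        rows.append({
            "rate": rate,
            "pcc_wnn": pcc_wnn,
            "pcc_gene_mean": pcc_base,
            "pcc_margin": pcc_wnn - pcc_base,
            "f1_wnn": f1_wnn,
            "f1_masked": f1_masked,
            "frac_cells_pcc_improved": frac_improved,
            "n_masked": int(len(rr)),
            "shrinkage": imputed.shrinkage,
        })
    return pd.DataFrame(rows)
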