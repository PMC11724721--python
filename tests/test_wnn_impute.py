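"""WNN graph construction and iterative imputation."""

import numpy as np
import pytest

import spvapa as sv
from spvapa import (
    ExprMatrix,
    PhiMatrix,
    embed,
    impute_pass,
    initial_fill,
    iterate_impute,
    modality_weights,
    normalize_expression,
)
from spvapa.wnn_impute import ModalityEmbedding, WNNGraph


def phi_from(values):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return PhiMatrix(values, [f"g{i}" for i in range(g)], [f"c{i}" for i in range(c)])


class TestNormalizeExpression:
    def test_zero_count_cell_named_in_error(self):
        G = ExprMatrix(np.array([[1.0, 0.0], [2.0, 0.0]]), ["g0", "g1"], ["good", "dead"])
        with pytest.raises(ValueError, match="dead"):
            normalize_expression(G)

    def test_proportional_cells_identical_profiles(self):
        G = ExprMatrix(np.array([[1.0, 3.0], [4.0, 12.0], [2.0, 6.0]]),
                       ["a", "b", "c"], ["c0", "c1"])
        X = normalize_expression(G)
        np.testing.assert_allclose(X[0], X[1], atol=1e-12)

    def test_log1p_of_median_scaled_counts(self):
        # depths 4 and 4 -> median 4, no rescale; log1p applied before z-scoring
        G = ExprMatrix(np.array([[1.0, 3.0], [3.0, 1.0]]), ["a", "b"], ["c0", "c1"])
        X = normalize_expression(G)
        raw = np.log1p([1.0, 3.0])
        expect = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(X[:, 0], expect)


class TestInitialFill:
    def test_gene_mean_fill(self):
        filled, _ = initial_fill(phi_from([[0.2, 0.4, np.nan]]))
        assert filled[0, 2] == pytest.approx(0.3)

    def test_fully_observed_unchanged(self):
        phi = phi_from([[0.2, 0.4], [0.1, 0.9]])
        filled, kept = initial_fill(phi)
        np.testing.assert_array_equal(filled, phi.values)
        assert kept.gene_ids == phi.gene_ids

    def test_all_missing_gene_dropped_with_warning(self):
        phi = phi_from([[np.nan, np.nan], [0.5, 0.6]])
        with pytest.warns(UserWarning, match="no observed"):
            filled, kept = initial_fill(phi)
        assert kept.gene_ids == ["g1"] and filled.shape == (1, 2)


class TestEmbed:
    def test_rank_deficient_second_component_null(self, rng):
        base = rng.normal(size=(10, 1))
        X = base @ np.array([[1.0, 2.0, -1.0]])  # rank 1
        e = embed(X, 2)
        assert np.var(e.coords[:, 1]) < 1e-20

    def test_rotation_invariant_variances(self, rng):
        X = rng.normal(size=(20, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        v1 = np.var(embed(X, 3).coords, axis=0)
        v2 = np.var(embed(X @ Q, 3).coords, axis=0)
        np.testing.assert_allclose(v1, v2, rtol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(4, 3))
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        scores_oracle = Xc @ evecs[:, order[:2]]
        e = embed(X, 2)
        for j in range(2):  # sign-free comparison per component
            a, b = e.coords[:, j], scores_oracle[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-10

    def test_excess_dimensions_truncated_with_warning(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.warns(UserWarning, match="truncated"):
            e = embed(X, 10)
        assert e.d == 2

    def test_incomplete_input_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            embed(np.array([[1.0, np.nan], [0.0, 1.0]]), 1)


class TestModalityWeights:
    def test_identical_modalities_weighted_half(self, rng):
        coords = rng.normal(size=(30, 3))
        g = modality_weights(ModalityEmbedding(coords, "expression"),
                             ModalityEmbedding(coords.copy(), "apa"), k=5)
        np.testing.assert_allclose(g.weights[:, 0], 0.5, atol=1e-12)

    def test_weights_sum_to_one_and_self_excluded(self, rng):
        e1 = ModalityEmbedding(rng.normal(size=(40, 3)), "expression")
        e2 = ModalityEmbedding(rng.normal(size=(40, 3)), "apa")
        g = modality_weights(e1, e2, k=6)
        np.testing.assert_allclose(g.weights.sum(axis=1), 1.0, atol=1e-12)
        assert all(i not in g.neighbors[i] for i in range(40))
        assert ((g.kernel_sims > 0) & (g.kernel_sims <= 1)).all()

    def test_informative_modality_gets_more_weight(self, rng):
        """Clustered expression vs pure-noise APA: expression should dominate."""
        n = 200
        centers = rng.normal(scale=8, size=(4, 5))
        expr = centers[np.arange(n) % 4] + rng.normal(size=(n, 5))
        apa = rng.normal(size=(n, 5))
        g = modality_weights(ModalityEmbedding(expr, "expression"),
                             ModalityEmbedding(apa, "apa"), k=20)
        assert g.weights[:, 0].mean() > 0.5

    def test_collinear_points_nearest_flank(self):
        coords = np.array([[0.0], [1.0], [3.0]])
        e = ModalityEmbedding(coords, "expression")
        g = modality_weights(e, ModalityEmbedding(coords.copy(), "apa"), k=1)
        assert g.neighbors[1, 0] == 0  # middle point's nearer flank

    def test_duplicate_cells_tie_break_by_index(self):
        coords = np.array([[0.0], [0.0], [5.0]])
        e = ModalityEmbedding(coords, "expression")
        g = modality_weights(e, ModalityEmbedding(coords.copy(), "apa"), k=2)
        assert list(g.neighbors[2]) == [0, 1]

    def test_k_at_least_n_rejected(self, rng):
        e = ModalityEmbedding(rng.normal(size=(5, 2)), "expression")
        with pytest.raises(ValueError, match="k="):
            modality_weights(e, e, k=5)


class TestImputePass:
    def make_graph(self, neighbors, sims):
        neighbors = np.asarray(neighbors)
        n, k = neighbors.shape
        return WNNGraph(neighbors, np.asarray(sims, dtype=float), np.full((n, 2), 0.5))

    def test_constant_neighbors_give_constant(self):
        phi = phi_from([[np.nan, 0.7, 0.7]])
        g = self.make_graph([[1, 2], [0, 2], [0, 1]], np.ones((3, 2)))
        out = impute_pass(phi, g)
        assert out.values[0, 0] == pytest.approx(0.7)

    def test_equal_similarity_average(self):
        phi = phi_from([[np.nan, 0.0, 1.0]])
        g = self.make_graph([[1, 2], [0, 2], [0, 1]], np.ones((3, 2)))
        assert impute_pass(phi, g).values[0, 0] == pytest.approx(0.5)

    def test_similarity_weighted_average(self):
        # neighbors (0.2, sim 0.9) and (0.8, sim 0.1) -> 0.26
        phi = phi_from([[np.nan, 0.2, 0.8]])
        g = self.make_graph([[1, 2], [0, 2], [0, 1]], [[0.9, 0.1], [1, 1], [1, 1]])
        assert impute_pass(phi, g).values[0, 0] == pytest.approx(0.26)

    def test_all_neighbors_missing_stays_missing(self):
        phi = phi_from([[np.nan, np.nan, 0.4]])
        g = self.make_graph([[1, 1], [0, 0], [0, 1]], np.ones((3, 2)))
        out = impute_pass(phi, g)
        assert out.mask[0, 0]  # neighbors of c0 observe nothing for this gene

    def test_observed_entries_untouched(self, rng):
        vals = rng.uniform(size=(5, 6))
        vals[rng.uniform(size=vals.shape) < 0.4] = np.nan
        phi = phi_from(vals)
        g = self.make_graph(np.array([[(i + 1) % 6, (i + 2) % 6] for i in range(6)]),
                            np.ones((6, 2)))
        out = impute_pass(phi, g)
        obs = ~phi.mask
        np.testing.assert_array_equal(out.values[obs], phi.values[obs])


class TestIterateImpute:
    def test_fully_observed_returns_input_zero_iters(self, rng):
        phi = phi_from(rng.uniform(size=(4, 12)))
        G = ExprMatrix(rng.integers(1, 20, size=(6, 12)).astype(float),
                       [f"e{i}" for i in range(6)], phi.cell_ids)
        res = iterate_impute(phi, G)
        assert res.n_iters == 0
        np.testing.assert_array_equal(res.phi_plus.values, phi.values)

    def test_infinite_tolerance_stops_after_one_pass(self, default_sim):
        res = iterate_impute(default_sim.phi, default_sim.expr, tol=np.inf,
                             calibrate=False)
        assert res.n_iters == 1 and res.converged

    def test_observed_entries_preserved_bit_exact(self, default_sim, default_imputed):
        phi = default_sim.phi
        plus = default_imputed.phi_plus.to_frame().reindex(phi.gene_ids).to_numpy()
        obs = ~phi.mask
        np.testing.assert_array_equal(plus[obs], phi.values[obs])

    def test_imputed_within_gene_observed_range(self, default_sim, default_imputed):
        phi = default_sim.phi
        lo = np.nanmin(phi.values, axis=1)
        hi = np.nanmax(phi.values, axis=1)
        vals = default_imputed.phi_plus.values
        assert ((vals >= lo[:, None] - 1e-12) & (vals <= hi[:, None] + 1e-12)).all()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_deterministic_rerun(self, default_sim, default_imputed):
        again = iterate_impute(default_sim.phi, default_sim.expr)
        np.testing.assert_array_equal(again.phi_plus.values,
                                      default_imputed.phi_plus.values)

    def test_beats_gene_mean_fill_on_masked_recovery(self, default_sim):
        """Core recovery claim at 50% extra masking, scored against truth."""
        phi_minus, G_minus, pos = sv.mask(default_sim.phi, default_sim.expr, 0.5, seed=1)
        rr, cc = pos[:, 0], pos[:, 1]
        truth = default_sim.truth.phi_true.values[rr, cc]
        res = iterate_impute(phi_minus, G_minus)
        base = sv.gene_mean_fill(phi_minus)
        pcc_wnn = np.corrcoef(res.phi_plus.values[rr, cc], truth)[0, 1]
        pcc_base = np.corrcoef(base.values[rr, cc], truth)[0, 1]
        assert pcc_wnn > pcc_base

    def test_mismatched_cells_rejected(self, rng):
        phi = phi_from(rng.uniform(size=(3, 4)))
        G = ExprMatrix(rng.integers(1, 9, size=(3, 4)).astype(float),
                       ["a", "b", "c"], ["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError, match="cell set"):
            iterate_impute(phi, G)
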