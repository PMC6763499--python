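import numpy as np
import pandas as pd
import pytest
import scipy.stats

from scsig import (
    GeneSignature,
    LatentSpace,
    build_backgrounds,
    compute_background_nulls,
    empirical_pvalues,
    geary_c,
    geary_c_batch,
    knn_from_latent,
    metadata_numeric_autocorrelation,
    score_all,
    signature_autocorrelation,
)
from scsig.autocorr import bh_fdr, rank_rows
from scsig.neighbors import NeighborGraph, weights_from_distances
from scsig.types import ExpressionMatrix, MetaData

from conftest import random_signature


def brute_force_geary(values, graph):
    """Dense O(N^2) double loop over the directed stored pairs."""
    n = len(values)
    w = np.zeros((n, n))
    for i in range(n):
        for j, wt in zip(graph.neighbor_index[i], graph.weight[i]):
            w[i, j] += wt
    num = sum(
        w[i, j] * (values[i] - values[j]) ** 2 for i in range(n) for j in range(n)
    )
    denom = 2 * w.sum() * ((values - values.mean()) ** 2).sum()
    return (n - 1) * num / denom


class TestGearyC:
    def test_two_separated_blobs_give_c_zero(self):
        # constant within-blob values and no cross-blob edges: numerator 0
        coords = np.vstack([np.random.default_rng(0).normal(0, 0.1, (10, 2)),
                            np.random.default_rng(1).normal(100, 0.1, (10, 2))])
        g = knn_from_latent(LatentSpace(coords, [f"c{i}" for i in range(20)]), k=3)
        values = np.repeat([0.0, 5.0], 10)
        assert geary_c(values, g) == pytest.approx(0.0, abs=1e-12)
        assert 1 - geary_c(values, g) == pytest.approx(1.0)

    def test_six_cell_toy_matches_double_loop(self):
        idx = np.array([[1, 2], [0, 3], [3, 0], [2, 5], [5, 1], [4, 2]])
        dist = np.array([[0.5, 1.0]] * 6)
        g = weights_from_distances(
            NeighborGraph(idx, dist, None, [f"c{i}" for i in range(6)])
        )
        values = np.array([0.3, -1.2, 2.0, 0.8, -0.5, 1.1])
        assert geary_c(values, g) == pytest.approx(brute_force_geary(values, g), abs=1e-12)

    def test_permuted_values_center_near_one(self, line_graph, rng):
        values = np.linspace(0, 1, line_graph.n_cells)
        cs = np.array(
            [1 - geary_c(rng.permutation(values), line_graph) for _ in range(200)]
        )
        assert abs(cs.mean()) < 3 * cs.std(ddof=1) / np.sqrt(200)

    def test_zero_variance_undefined(self, line_graph):
        assert np.isnan(geary_c(np.ones(line_graph.n_cells), line_graph))

    def test_batch_matches_single(self, line_graph, rng):
        mat = rng.normal(size=(7, line_graph.n_cells))
        batch = geary_c_batch(mat, line_graph, chunk=3)
        single = [geary_c(row, line_graph) for row in mat]
        np.testing.assert_allclose(batch, single, atol=1e-12)


class TestSignatureAutocorrelation:
    def test_monotone_scores_on_chain_are_smooth(self, line_graph):
        scores = np.arange(line_graph.n_cells, dtype=float)[None, :]
        from scsig.scoring import SignatureScoreMatrix

        ssm = SignatureScoreMatrix(scores, ["grad"], line_graph.cell_ids)
        df = signature_autocorrelation(ssm, line_graph)
        assert df["c_prime"].iloc[0] > 0.9

    def test_iid_scores_near_zero(self, line_graph, rng):
        from scsig.scoring import SignatureScoreMatrix

        mat = rng.normal(size=(50, line_graph.n_cells))
        ssm = SignatureScoreMatrix(mat, [f"s{i}" for i in range(50)], line_graph.cell_ids)
        cps = signature_autocorrelation(ssm, line_graph)["c_prime"]
        assert abs(cps.mean()) < 3 * cps.std(ddof=1) / np.sqrt(50)

    def test_rank_invariance_under_monotone_transform(self, line_graph, rng):
        from scsig.scoring import SignatureScoreMatrix

        x = rng.normal(size=line_graph.n_cells)
        a = SignatureScoreMatrix(x[None], ["a"], line_graph.cell_ids)
        b = SignatureScoreMatrix(np.exp(3 * x)[None], ["a"], line_graph.cell_ids)
        ca = signature_autocorrelation(a, line_graph)["c_prime"].iloc[0]
        cb = signature_autocorrelation(b, line_graph)["c_prime"].iloc[0]
        assert ca == pytest.approx(cb, abs=1e-12)


class TestBackgrounds:
    def test_seeded_determinism_bit_identical(self, rng):
        sigs = [random_signature(rng, [f"g{i}" for i in range(200)], 10 + i, name=f"s{i}") for i in range(6)]
        g1, a1 = build_backgrounds(sigs, [f"g{i}" for i in range(200)], n_per_group=20, seed=3)
        g2, a2 = build_backgrounds(sigs, [f"g{i}" for i in range(200)], n_per_group=20, seed=3)
        np.testing.assert_array_equal(a1, a2)
        for x, y in zip(g1, g2):
            assert [s.positive_genes for s in x.signatures] == [
                s.positive_genes for s in y.signatures
            ]

    def test_groups_separate_size_scales(self, rng):
        universe = [f"g{i}" for i in range(2000)]
        sigs = [random_signature(rng, universe, 10, name=f"small{i}") for i in range(5)]
        sigs += [random_signature(rng, universe, 1000, name=f"big{i}") for i in range(5)]
        groups, assignment = build_backgrounds(sigs, universe, n_per_group=5, seed=0)
        for sig, g in zip(sigs, assignment):
            assert 0.5 <= groups[g].size / sig.size <= 2.0

    def test_oversized_center_capped(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sigs = [GeneSignature(f"s{i}", frozenset(universe[:45])) for i in range(5)]
        with pytest.warns(UserWarning, match="capped"):
            groups, _ = build_backgrounds(sigs, universe[:40], n_per_group=3, seed=0)
        assert all(g.size <= 40 for g in groups)

    def test_signed_balance_respected(self, rng):
        universe = [f"g{i}" for i in range(300)]
        sigs = [
            GeneSignature(f"s{i}", frozenset(universe[:20]), frozenset(universe[20:40]))
            for i in range(5)
        ]
        groups, _ = build_backgrounds(sigs, universe, n_per_group=4, seed=1)
        for g in groups:
            for s in g.signatures:
                assert len(s.positive_genes) == g.n_pos
                assert s.size == g.size


class TestEmpiricalPvalues:
    def _groups(self, null):
        from scsig.autocorr import BackgroundGroup

        g = BackgroundGroup(1.0, 1.0, 10, 10, [], c_prime_null=np.asarray(null, float))
        return [g]

    def test_observed_above_all_nulls(self):
        obs = pd.DataFrame({"signature": ["s"], "c_prime": [0.9]})
        out = empirical_pvalues(obs, self._groups(np.linspace(0, 0.5, 100)), np.array([0]))
        assert out["p_value"].iloc[0] == pytest.approx(1 / 101)

    def test_observed_below_all_nulls(self):
        obs = pd.DataFrame({"signature": ["s"], "c_prime": [-0.2]})
        out = empirical_pvalues(obs, self._groups(np.linspace(0, 0.5, 100)), np.array([0]))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_fdr_at_least_p(self, rng):
        obs = pd.DataFrame(
            {"signature": [f"s{i}" for i in range(20)], "c_prime": rng.uniform(0, 0.6, 20)}
        )
        out = empirical_pvalues(obs, self._groups(rng.uniform(0, 0.6, 200)), np.zeros(20, int))
        assert np.all(out["fdr"] >= out["p_value"] - 1e-12)


class TestBH:
    def test_step_up_properties_hold_for_arbitrary_pvectors(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=50, deadline=None)
        @given(
            st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=30)
        )
        def check(p_list):
            p = np.array(p_list)
            adj = bh_fdr(p)
            assert np.all((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12))
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in p

        check()

    def test_hand_computed_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(bh_fdr(p), [0.004, 0.02, 4 * 0.02 / 3, 0.8], atol=1e-12)

    def test_matches_textbook_step_up_on_random_vectors(self, rng):
        def step_up(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), step_up(p), atol=1e-12)


class TestNumericMetadata:
    def test_planted_gradient_maximally_significant(self, line_graph):
        meta = MetaData(
            line_graph.cell_ids,
            numeric=pd.DataFrame(
                {"grad": np.arange(line_graph.n_cells, dtype=float)},
                index=line_graph.cell_ids,
            ),
        )
        out = metadata_numeric_autocorrelation(meta, line_graph, n_perm=99, seed=0)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 100)

    def test_constant_column_is_nan(self, line_graph):
        meta = MetaData(
            line_graph.cell_ids,
            numeric=pd.DataFrame(
                {"flat": np.ones(line_graph.n_cells)}, index=line_graph.cell_ids
            ),
        )
        with pytest.warns(UserWarning, match="constant"):
            out = metadata_numeric_autocorrelation(meta, line_graph, n_perm=20, seed=0)
        assert np.isnan(out["p_value"].iloc[0])

    def test_within_stratum_permutation_removes_between_group_signal(self):
        # two "donors" occupy the two halves of a line; the numeric column
        # is a pure donor offset, so within-donor permutations reproduce it
        n = 60
        coords = np.arange(n, dtype=float)[:, None]
        g = knn_from_latent(LatentSpace(coords, [f"c{i}" for i in range(n)]), k=5)
        donor = np.repeat(["d1", "d2"], n // 2)
        column = np.repeat([0.0, 10.0], n // 2) + np.random.default_rng(4).normal(0, 0.1, n)
        meta = MetaData(
            g.cell_ids,
            numeric=pd.DataFrame({"offset": column}, index=g.cell_ids),
            categorical=pd.DataFrame({"donor": donor}, index=g.cell_ids),
        )
        naive = metadata_numeric_autocorrelation(meta, g, n_perm=99, seed=0)
        strat = metadata_numeric_autocorrelation(
            meta, g, n_perm=99, seed=0, stratify_by="donor"
        )
        assert naive["p_value"].iloc[0] < 0.05
        assert strat["p_value"].iloc[0] > 0.1


class TestPipelineNullCalibration:
    def test_background_nulls_flow_through_scoring_path(self, rng):
        expr = ExpressionMatrix(
            rng.gamma(2, 1, size=(150, 60)),
            [f"g{i}" for i in range(150)],
            [f"c{j}" for j in range(60)],
        )
        sigs = [random_signature(rng, expr.gene_ids, 15, name=f"s{i}") for i in range(5)]
        groups, assignment = build_backgrounds(sigs, expr.gene_ids, n_per_group=30, seed=0)
        from scsig import pca_latent

        graph = knn_from_latent(pca_latent(expr, 5, seed=0))
        compute_background_nulls(expr, graph, groups)
        for g in groups:
            assert g.c_prime_null.shape == (30,)
            assert np.all(np.isfinite(g.c_prime_null))
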