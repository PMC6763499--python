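import numpy as np
import pytest

from scsig import ExpressionMatrix, GeneSignature, corrected_score, raw_score, score_all
from scsig.scoring import cell_moments, gene_signature_covariance

from conftest import random_signature


def brute_force_score(expr, sig):
    """Independent per-cell re-summation of the raw score."""
    out = np.zeros(expr.n_cells)
    used = 0
    upper = {g.upper(): i for i, g in enumerate(expr.gene_ids)}
    for g in sig.positive_genes:
        if g.upper() in upper:
            out += expr.values[upper[g.upper()]]
            used += 1
    for g in sig.negative_genes:
        if g.upper() in upper:
            out -= expr.values[upper[g.upper()]]
            used += 1
    return out / used


class TestRawScore:
    def test_single_gene_identity(self):
        expr = ExpressionMatrix([[2.0, 3.0]], ["A"], ["c1", "c2"])
        s, n, m = raw_score(expr, GeneSignature("s", {"A"}))
        np.testing.assert_allclose(s, [2.0, 3.0])
        assert (n, m) == (1, 0)

    def test_signed_two_gene_formula(self):
        expr = ExpressionMatrix([[3.0], [1.0]], ["A", "B"], ["c1"])
        s, n, m = raw_score(expr, GeneSignature("s", {"A"}, {"B"}))
        assert s[0] == pytest.approx((3 - 1) / 2)

    def test_matches_brute_force_on_random_signature(self, rng):
        expr = ExpressionMatrix(
            rng.gamma(2, 1, size=(100, 40)),
            [f"g{i}" for i in range(100)],
            [f"c{j}" for j in range(40)],
        )
        sig = random_signature(rng, expr.gene_ids, n_pos=10, n_neg=5)
        s, _, _ = raw_score(expr, sig)
        np.testing.assert_allclose(s, brute_force_score(expr, sig), atol=1e-12)

    def test_case_insensitive_matching(self):
        expr = ExpressionMatrix([[1.0], [2.0]], ["Actb", "CD4"], ["c1"])
        s, n, _ = raw_score(expr, GeneSignature("s", {"ACTB", "cd4"}))
        assert n == 2
        assert s[0] == pytest.approx(1.5)

    def test_no_usable_genes_raises(self, small_expr):
        with pytest.raises(ValueError, match="no genes"):
            raw_score(small_expr, GeneSignature("s", {"MISSING"}))

    def test_union_linearity_over_disjoint_unsigned_sets(self, small_expr, rng):
        a = random_signature(rng, small_expr.gene_ids[:25], 10, name="a")
        b = random_signature(rng, small_expr.gene_ids[25:], 15, name="b")
        union = GeneSignature("u", a.positive_genes | b.positive_genes)
        sa, na, _ = raw_score(small_expr, a)
        sb, nb, _ = raw_score(small_expr, b)
        su, _, _ = raw_score(small_expr, union)
        np.testing.assert_allclose(su, (na * sa + nb * sb) / (na + nb), atol=1e-12)


class TestCorrectedScore:
    def test_balanced_signed_signature_has_zero_expected_offset(self, small_expr):
        # n == m: the random-signature expectation vanishes, so correction
        # is a pure rescale by sqrt(var/size)
        raw = np.linspace(-1, 1, small_expr.n_cells)
        _, var = cell_moments(small_expr)
        out = corrected_score(raw, small_expr, n_pos=5, n_neg=5)
        np.testing.assert_allclose(out, raw / np.sqrt(var / 10), atol=1e-12)

    def test_score_at_expectation_maps_to_zero(self, small_expr):
        mean, _ = cell_moments(small_expr)
        out = corrected_score(mean.copy(), small_expr, n_pos=1, n_neg=0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constant_cell_flagged_and_zeroed(self):
        expr = ExpressionMatrix([[1.0, 1.0], [1.0, 2.0]], ["a", "b"], ["c1", "c2"])
        with pytest.warns(UserWarning, match="constant-expression"):
            out = corrected_score(np.array([5.0, 5.0]), expr, 1, 0)
        assert out[0] == 0.0
        assert out[1] != 0.0

    def test_duplicated_cells_get_identical_corrected_scores(self, small_expr, rng):
        sig = random_signature(rng, small_expr.gene_ids, 8, 4)
        doubled = ExpressionMatrix(
            np.hstack([small_expr.values, small_expr.values[:, :5]]),
            small_expr.gene_ids,
            small_expr.cell_ids + [f"dup{i}" for i in range(5)],
        )
        scores = score_all(doubled, [sig]).scores[0]
        np.testing.assert_allclose(scores[-5:], scores[:5], atol=1e-12)

    def test_random_signature_moments_calibrate(self, rng):
        # law-of-large-numbers check of the analytic E[R], var(R) at one cell
        expr = ExpressionMatrix(
            rng.gamma(2, 1, size=(400, 20)),
            [f"g{i}" for i in range(400)],
            [f"c{j}" for j in range(20)],
        )
        draws = np.array(
            [
                score_all(expr, [random_signature(rng, expr.gene_ids, 30, 10)]).scores[0]
                for _ in range(400)
            ]
        )
        se = 1.0 / np.sqrt(400)
        assert np.all(np.abs(draws.mean(axis=0)) < 4 * se)
        assert 0.7 < np.median(draws.var(axis=0)) < 1.3


class TestScoreAll:
    def test_batch_of_one_equals_corrected_single(self, small_expr, rng):
        sig = random_signature(rng, small_expr.gene_ids, 10, 5)
        s, n, m = raw_score(small_expr, sig)
        expected = corrected_score(s, small_expr, n, m)
        got = score_all(small_expr, [sig]).scores[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_batch_equals_per_signature_loop(self, small_expr, rng):
        sigs = [
            random_signature(rng, small_expr.gene_ids, 5 + i, i, name=f"s{i}")
            for i in range(4)
        ]
        batch = score_all(small_expr, sigs)
        for i, sig in enumerate(sigs):
            s, n, m = raw_score(small_expr, sig)
            np.testing.assert_allclose(
                batch.scores[i], corrected_score(s, small_expr, n, m), atol=1e-12
            )

    def test_duplicate_names_error(self, small_expr):
        sig = GeneSignature("dup", {"g1"})
        with pytest.raises(ValueError, match="duplicate"):
            score_all(small_expr, [sig, GeneSignature("dup", {"g2"})])

    def test_empty_list_error(self, small_expr):
        with pytest.raises(ValueError):
            score_all(small_expr, [])

    def test_unmatched_signature_dropped_with_report(self, small_expr):
        sigs = [GeneSignature("ok", {"g1", "g2"}), GeneSignature("gone", {"ZZZ"})]
        with pytest.warns(UserWarning, match="dropped"):
            out = score_all(small_expr, sigs)
        assert out.signature_names == ["ok"]
        assert "gone" in out.dropped


class TestGeneSignatureCovariance:
    def test_constant_gene_has_zero_covariance(self):
        expr = ExpressionMatrix(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], ["flat", "var"], ["c1", "c2", "c3"]
        )
        sig = GeneSignature("s", {"flat", "var"})
        scores = score_all(expr, [sig]).scores[0]
        cov = gene_signature_covariance(expr, scores, sig)
        assert cov["flat"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_covariance(self, small_expr, rng):
        sig = random_signature(rng, small_expr.gene_ids, 6, 3)
        scores = score_all(small_expr, [sig]).scores[0]
        cov = gene_signature_covariance(small_expr, scores, sig)
        for gene in list(sig.positive_genes)[:3]:
            row = small_expr.values[small_expr.gene_ids.index(gene)]
            direct = np.mean((row - row.mean()) * (scores - scores.mean()))
            assert cov[gene] == pytest.approx(direct, abs=1e-12)

    def test_anticorrelated_negative_gene_is_negative(self):
        up = np.linspace(0, 4, 20)
        expr = ExpressionMatrix(
            np.vstack([up, 4 - up]), ["pos", "neg"], [f"c{i}" for i in range(20)]
        )
        sig = GeneSignature("s", {"pos"}, {"neg"})
        scores = score_all(expr, [sig]).scores[0]
        cov = gene_signature_covariance(expr, scores, sig)
        assert cov["neg"] < 0

    def test_too_few_cells_error(self):
        expr = ExpressionMatrix([[1.0]], ["g"], ["c"])
        with pytest.raises(ValueError):
            gene_signature_covariance(expr, np.array([1.0]), GeneSignature("s", {"g"}))
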