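import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import squareform

from genelang import (
    DistanceMatrix,
    mantel,
    offdiag_vector,
    partial_mantel,
    partial_pearson,
    residual_mantel,
)

from ._oracles import (
    mantel_exact,
    partial_corr_naive,
    partial_mantel_exact,
    t_pvalue_betainc,
)
from .conftest import make_random_dm


def _dm_from_vec(vec, ids, kind="generic"):
    return DistanceMatrix(squareform(np.asarray(vec, float)), ids, kind)


class TestOffdiag:
    def test_row_major_order(self):
        d = _dm_from_vec([1.0, 2.0, 3.0], list("abc"))
        assert offdiag_vector(d).tolist() == [1.0, 2.0, 3.0]

    def test_length(self, rng):
        assert offdiag_vector(make_random_dm(rng, 5)).size == 10

    def test_relabeling_preserves_multiset(self, rng):
        d = make_random_dm(rng, 6)
        perm = rng.permutation(d.ids).tolist()
        shuffled = d.filter(perm)
        assert sorted(offdiag_vector(d)) == pytest.approx(
            sorted(offdiag_vector(shuffled))
        )


class TestMantel:
    def test_self_correlation_is_one_with_minimal_p(self, rng):
        a = make_random_dm(rng, 8)
        res = mantel(a, a, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_anti_identity(self, rng):
        a = make_random_dm(rng, 7)
        b = DistanceMatrix(
            np.where(np.eye(7, dtype=bool), 0.0, 5.0 - a.values), a.ids
        )
        res = mantel(a, b, n_perm=0)
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_permutations_returns_no_p(self, rng):
        res = mantel(make_random_dm(rng, 5), make_random_dm(rng, 5), n_perm=0)
        assert res.p_value is None and res.n_permutations == 0

    def test_zero_variance_errors(self, rng):
        a = make_random_dm(rng, 5)
        flat = _dm_from_vec(np.ones(10), a.ids)
        with pytest.raises(ValueError, match="zero variance"):
            mantel(a, flat, n_perm=9, seed=0)

    def test_unaligned_ids_rejected(self, rng):
        a = make_random_dm(rng, 5, ids=list("abcde"))
        b = make_random_dm(rng, 5, ids=list("edcba"))
        with pytest.raises(ValueError, match="aligned"):
            mantel(a, b, n_perm=9)

    def test_seeded_p_reproducible(self, rng):
        a, b = make_random_dm(rng, 8), make_random_dm(rng, 8)
        r1 = mantel(a, b, n_perm=999, seed=42)
        r2 = mantel(a, b, n_perm=999, seed=42)
        assert r1.p_value == r2.p_value and r1.r == r2.r

    def test_monte_carlo_p_matches_exhaustive_enumeration(self, rng):
        a, b = make_random_dm(rng, 5), make_random_dm(rng, 5)
        r_exact, p_exact = mantel_exact(a.values, b.values)
        res = mantel(a, b, n_perm=5_000, seed=3)
        assert res.r == pytest.approx(r_exact, abs=1e-10)
        se = np.sqrt(p_exact * (1 - p_exact) / 5_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1 / 5_001

    def test_agrees_with_skbio_reference(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a, b = make_random_dm(rng, 9), make_random_dm(rng, 9)
        r_skbio, p_skbio, _ = skbio_mantel(
            SkbioDM(a.values, a.ids), SkbioDM(b.values, b.ids),
            method="pearson", permutations=3_000, alternative="greater",
        )
        res = mantel(a, b, n_perm=3_000, seed=8)
        assert res.r == pytest.approx(r_skbio, abs=1e-12)
        se = np.sqrt(max(p_skbio * (1 - p_skbio), 1e-6) / 3_000)
        assert abs(res.p_value - p_skbio) <= 4 * se + 2 / 3_000

    @given(alpha=st.floats(0.1, 10.0), beta=st.floats(-5.0, 5.0))
    def test_affine_invariance_of_r(self, alpha, beta):
        rng = np.random.default_rng(99)
        a, b = make_random_dm(rng, 6), make_random_dm(rng, 6)
        vals = alpha * b.values + beta
        np.fill_diagonal(vals, 0.0)
        b2 = DistanceMatrix(vals, b.ids)
        assert mantel(a, b2, n_perm=0).r == pytest.approx(
            mantel(a, b, n_perm=0).r, abs=1e-9
        )

    def test_relabeling_invariance_of_r(self, rng):
        a, b = make_random_dm(rng, 7), make_random_dm(rng, 7)
        order = rng.permutation(a.ids).tolist()
        r1 = mantel(a, b, n_perm=0).r
        r2 = mantel(a.filter(order), b.filter(order), n_perm=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPartialMantel:
    def test_orthogonal_control_leaves_r_unchanged(self, rng):
        # build c whose condensed vector is orthogonal (after centering)
        # to both a's and b's
        a, b = make_random_dm(rng, 6), make_random_dm(rng, 6)
        va, vb = offdiag_vector(a), offdiag_vector(b)
        m = va.size
        q, _ = np.linalg.qr(np.column_stack(
            [np.ones(m), va - va.mean(), vb - vb.mean(), rng.random(m)]
        ))
        vc = q[:, 3] + 1.0  # orthogonal to centred va, vb; positive shift
        c = _dm_from_vec(vc, a.ids)
        r_plain = mantel(a, b, n_perm=0).r
        r_part = partial_mantel(a, b, c, n_perm=0).r
        assert r_part == pytest.approx(r_plain, abs=1e-10)

    def test_matches_textbook_partial_correlation(self, rng):
        a, b, c = (make_random_dm(rng, 6) for _ in range(3))
        expected = partial_corr_naive(
            offdiag_vector(a), offdiag_vector(b), offdiag_vector(c)
        )
        assert partial_mantel(a, b, c, n_perm=0).r == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_control_errors(self, rng):
        a, b = make_random_dm(rng, 6), make_random_dm(rng, 6)
        flat = _dm_from_vec(np.ones(15), a.ids)
        with pytest.raises(ValueError, match="zero variance"):
            partial_mantel(a, b, flat, n_perm=9, seed=0)

    def test_near_constant_control_approaches_plain_r(self, rng):
        # correlation is scale-invariant, so a jittered constant still has
        # r_ac, r_bc ~ 1/sqrt(m); the partial r approaches the plain r at
        # the quadratic rate the formula implies as m grows
        n = 30
        a, b = make_random_dm(rng, n), make_random_dm(rng, n)
        m = n * (n - 1) // 2
        jitter = _dm_from_vec(1.0 + 1e-9 * rng.random(m), a.ids)
        r_plain = mantel(a, b, n_perm=0).r
        r_part = partial_mantel(a, b, jitter, n_perm=0).r
        r_ac = mantel(a, jitter, n_perm=0).r
        r_bc = mantel(b, jitter, n_perm=0).r
        bound = abs(r_ac * r_bc) + abs(r_plain) * (r_ac**2 + r_bc**2) + 1e-10
        assert abs(r_part - r_plain) <= 2 * bound

    def test_collinear_control_rejected(self, rng):
        a, b = make_random_dm(rng, 6), make_random_dm(rng, 6)
        with pytest.raises(ValueError, match="collinear"):
            partial_mantel(a, b, a, n_perm=9, seed=0)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self, rng):
        a, b, c = (make_random_dm(rng, 5) for _ in range(3))
        r_exact, p_exact = partial_mantel_exact(a.values, b.values, c.values)
        res = partial_mantel(a, b, c, n_perm=5_000, seed=4)
        assert res.r == pytest.approx(r_exact, abs=1e-10)
        se = np.sqrt(p_exact * (1 - p_exact) / 5_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1 / 5_001


class TestPartialPearson:
    def test_zero_partial_r_gives_p_one(self, rng):
        # engineer r_ab.c = 0 by making vb orthogonal to va with vc noise
        a = make_random_dm(rng, 6)
        va = offdiag_vector(a)
        m = va.size
        q, _ = np.linalg.qr(np.column_stack(
            [np.ones(m), va - va.mean(), rng.random(m), rng.random(m)]
        ))
        b = _dm_from_vec(q[:, 2] + 1.0, a.ids)
        c = _dm_from_vec(q[:, 3] + 1.0, a.ids)
        res = partial_pearson(a, b, c)
        assert res.r == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_identical_matrices_flagged_degenerate(self, rng):
        a = make_random_dm(rng, 6)
        c = make_random_dm(rng, 6)
        res = partial_pearson(a, a, c)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p_value < 1e-200
        assert "degenerate" in res.note

    def test_p_matches_incomplete_beta_oracle(self, rng):
        a, b, c = (make_random_dm(rng, 7) for _ in range(3))
        res = partial_pearson(a, b, c)
        m = 21
        t = res.r * np.sqrt((m - 3) / (1 - res.r**2))
        assert res.p_value == pytest.approx(
            t_pvalue_betainc(t, m - 3, two_sided=True), abs=1e-10
        )
        assert res.parametric


class TestResidualMantel:
    def test_control_equal_to_focal_gives_zero_variance(self, rng):
        a = make_random_dm(rng, 6)
        b = make_random_dm(rng, 6)
        with pytest.raises(ValueError):
            residual_mantel(a, b, a, n_perm=9, seed=0)

    def test_observed_r_equals_partial_mantel(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 11))
            a, b, c = (make_random_dm(rng, n) for _ in range(3))
            r_res = residual_mantel(a, b, c, n_perm=0).r
            r_par = partial_mantel(a, b, c, n_perm=0).r
            assert r_res == pytest.approx(r_par, abs=1e-12)

    def test_permutation_p_within_monte_carlo_error_of_partial(self, rng):
        a, b, c = (make_random_dm(rng, 8) for _ in range(3))
        p_res = residual_mantel(a, b, c, n_perm=4_000, seed=5).p_value
        p_par = partial_mantel(a, b, c, n_perm=4_000, seed=6).p_value
        p = (p_res + p_par) / 2
        se = np.sqrt(max(p * (1 - p), 1e-4) / 4_000)
        assert abs(p_res - p_par) <= 4 * np.sqrt(2) * se

    def test_method_label(self, rng):
        a, b, c = (make_random_dm(rng, 6) for _ in range(3))
        assert residual_mantel(a, b, c, n_perm=9, seed=0).method == "residual_mantel"


def test_permutation_p_never_zero(rng):
    a = make_random_dm(rng, 8)
    res = mantel(a, a, n_perm=499, seed=0)
    assert res.p_value >= 1 / 500
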