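"""Mantel test and partial-correlation procedures with permutation nulls.

Four related procedures for testing the association of two labelled
distance matrices, the latter three controlling for a third matrix
(geographic distance, in the gene-language application):

``mantel``
    Pearson correlation of the off-diagonal (condensed) vectors, null built
    by simultaneous row/column relabelling.
``partial_mantel``
    First-order partial correlation r_ab.c on condensed vectors; the first
    matrix is relabelled and the partial statistic recomputed under the
    null.
``partial_pearson``
    Same observed statistic, parametric p from Student's t treating the
    n(n-1)/2 pairs as independent (they are not — the result carries that
    caveat).
``residual_mantel``
    The Smouse-Long-Sokal procedure: regress each focal matrix on the
    control, reassemble the residuals into symmetric matrices, Mantel-test
    the residual matrices.

All permutation p-values use the add-one estimator
``p = (1 + #{r_perm >= r_obs}) / (1 + B)`` so p is never exactly 0 and ties
count toward the numerator (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform

from .containers import DistanceMatrix

__all__ = [
    "MantelResult",
    "offdiag_vector",
    "mantel",
    "partial_mantel",
    "partial_pearson",
    "residual_mantel",
    "partial_correlation",
]

_ALTERNATIVES = ("greater", "two_sided")


@dataclass
class MantelResult:
    """Observed statistic and (permutation or parametric) p-value.

    ``r`` is always the statistic of the unpermuted data.  For permutation
    methods ``p_value >= 1/(n_permutations+1)``; ``p_value`` is None when
    ``n_permutations == 0`` and no parametric test applies.
    """

    r: float
    p_value: Optional[float]
    n_permutations: int
    alternative: str
    method: str
    n: int
    seed: Optional[int] = None
    parametric: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"statistic {self.r} outside [-1, 1]")


def offdiag_vector(d: DistanceMatrix) -> np.ndarray:
    """The n(n-1)/2 upper-triangle entries in fixed row-major order."""
    if d.n < 3:
        raise ValueError("need at least 3 populations")
    return d.condensed()


def _check_aligned(*mats: DistanceMatrix) -> None:
    ids0 = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids0:
            raise ValueError(
                "distance matrices are not aligned; use align_matrices first"
            )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0.0:
        raise ValueError("zero variance in an off-diagonal vector")
    return float((xc @ yc) / den)


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with fixed ``y``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = rc @ yc
    den = np.sqrt((rc * rc).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den

def _permutation_indices(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(perms, axis=1)


def _permuted_condensed(
    values: np.ndarray, perms: np.ndarray, iu: tuple
) -> np.ndarray:
    """Condensed vectors of ``values`` under each row/column relabelling."""
    return values[perms[:, iu[0]], perms[:, iu[1]]]


def _perm_pvalue(
    r_obs: float, r_perm: np.ndarray, alternative: str
) -> tuple[float, int]:
    ok = np.isfinite(r_perm)
    r_perm = r_perm[ok]
    if alternative == "greater":
        count = int(np.sum(r_perm >= r_obs))
    else:
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs)))
    return (1 + count) / (1 + r_perm.size), r_perm.size


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10_000,
    alternative: str = "greater",
    seed=None,
    _method: str = "mantel",
) -> MantelResult:
    """Mantel test between two aligned distance matrices.

    The observed statistic is the Pearson correlation of the two condensed
    vectors; the null distribution is built by permuting rows and columns
    of ``b`` simultaneously ``n_perm`` times.  ``n_perm=0`` returns the
    statistic with no p-value.  ``seed`` may be an int or a numpy
    Generator.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    _check_aligned(a, b)
    n = a.n
    va = offdiag_vector(a)
    vb = offdiag_vector(b)
    r_obs = _pearson(va, vb)
    if n_perm == 0:
        return MantelResult(r_obs, None, 0, alternative, _method, n, _seed_int(seed))
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    perms = _permutation_indices(n, n_perm, rng)
    vb_perm = _permuted_condensed(b.values, perms, iu)
    r_perm = _pearson_rows(vb_perm, va)
    p, used = _perm_pvalue(r_obs, r_perm, alternative)
    return MantelResult(r_obs, p, used, alternative, _method, n, _seed_int(seed))


def partial_correlation(va: np.ndarray, vb: np.ndarray, vc: np.ndarray) -> float:
    """First-order partial correlation r_ab.c of three vectors."""
    r_ab = _pearson(va, vb)
    r_ac = _pearson(va, vc)
    r_bc = _pearson(vb, vc)
    if abs(r_ac) >= 1.0 or abs(r_bc) >= 1.0:
        raise ValueError(
            "control matrix is collinear with a focal matrix "
            f"(|r_ac|={abs(r_ac):.3f}, |r_bc|={abs(r_bc):.3f})"
        )
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 10_000,
    alternative: str = "greater",
    seed=None,
) -> MantelResult:
    """Partial Mantel test of ``a`` vs ``b`` controlling for ``c``.

    The observed statistic is the first-order partial correlation
    r_ab.c of the condensed vectors.  Under the null the first matrix
    ``a`` is relabelled (rows and columns simultaneously) and the partial
    statistic recomputed each time; the choice of which matrix to permute
    is a documented convention and is symmetric under swapping a and b.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    _check_aligned(a, b, c)
    n = a.n
    if n < 4:
        raise ValueError("partial tests need at least 4 populations")
    va, vb, vc = (offdiag_vector(m) for m in (a, b, c))
    r_obs = partial_correlation(va, vb, vc)
    if n_perm == 0:
        return MantelResult(
            r_obs, None, 0, alternative, "partial_mantel", n, _seed_int(seed)
        )
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    perms = _permutation_indices(n, n_perm, rng)
    va_perm = _permuted_condensed(a.values, perms, iu)
    r_bc = _pearson(vb, vc)
    r_ab_p = _pearson_rows(va_perm, vb)
    r_ac_p = _pearson_rows(va_perm, vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (r_ab_p - r_ac_p * r_bc) / np.sqrt(
            (1 - r_ac_p**2) * (1 - r_bc**2)
        )
    p, used = _perm_pvalue(r_obs, r_perm, alternative)
    return MantelResult(
        r_obs, p, used, alternative, "partial_mantel", n, _seed_int(seed)
    )


def partial_pearson(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    alternative: str = "two_sided",
) -> MantelResult:
    """Parametric partial Pearson correlation of two distance matrices.

    Same observed statistic as :func:`partial_mantel`; the p-value comes
    from ``t = r sqrt((m-3)/(1-r^2))`` with ``m = n(n-1)/2`` pairs treated
    as independent observations.  Distance pairs sharing a population are
    not independent, so this p-value is anti-conservative; the result is
    flagged ``parametric`` with that caveat in ``note``.
    """
    _check_aligned(a, b, c)
    n = a.n
    m = n * (n - 1) // 2
    if m <= 3:
        raise ValueError("need more than 3 distance pairs")
    va, vb, vc = (offdiag_vector(x) for x in (a, b, c))
    r = partial_correlation(va, vb, vc)
    df = m - 3
    note = "parametric p treats distance pairs as independent (they are not)"
    if abs(r) >= 1.0:
        p = float(np.nextafter(0.0, 1.0))
        note += "; degenerate |r|=1"
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        if alternative == "two_sided":
            p = float(2.0 * stats.t.sf(abs(t), df))
        else:
            p = float(stats.t.sf(t, df))
    return MantelResult(
        r, p, 0, alternative, "partial_pearson", n, None, parametric=True, note=note
    )


def _residual_matrix(y: DistanceMatrix, x: DistanceMatrix) -> DistanceMatrix:
    """OLS residuals (with intercept) of y's condensed vector on x's,
    reassembled into a symmetric zero-diagonal matrix."""
    vy = offdiag_vector(y)
    vx = offdiag_vector(x)
    design = np.column_stack([np.ones_like(vx), vx])
    beta, *_ = np.linalg.lstsq(design, vy, rcond=None)
    resid = vy - design @ beta
    return DistanceMatrix(squareform(resid), y.ids, kind="residual")


def residual_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 10_000,
    alternative: str = "greater",
    seed=None,
) -> MantelResult:
    """Residual-matrix (Smouse) partial Mantel test.

    Regress ``a`` on ``c`` and ``b`` on ``c`` (condensed vectors, with
    intercept), reshape the residuals into symmetric matrices and run a
    plain Mantel test between them.  The observed statistic equals the
    partial correlation r_ab.c exactly (residual correlation identity).
    """
    _check_aligned(a, b, c)
    if a.n < 4:
        raise ValueError("partial tests need at least 4 populations")
    # reject degenerate controls the same way partial_mantel does
    partial_correlation(*(offdiag_vector(m) for m in (a, b, c)))
    res_a = _residual_matrix(a, c)
    res_b = _residual_matrix(b, c)
    return mantel(
        res_a, res_b, n_perm=n_perm, alternative=alternative, seed=seed,
        _method="residual_mantel",
    )


def _seed_int(seed) -> Optional[int]:
    return seed if isinstance(seed, (int, np.integer)) else None
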