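"""PCA ordination and Procrustes comparison of 2-D configurations.

A genetic or linguistic table is reduced to its first two principal
components and compared to the geographic map (longitude/latitude treated
as planar coordinates) by Procrustes superimposition: both configurations
are centred and scaled to unit sum of squares, then one is optimally
rotated (reflections permitted), scaled and translated onto the other.
The similarity score is ``t0 = sqrt(1 - D)`` where ``D`` is the minimised
normalised sum of squared deviations; its significance comes from
permuting the row order of the geographic configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

__all__ = ["ProcrustesResult", "pca_scores", "procrustes_fit", "procrustes_test"]


@dataclass
class ProcrustesResult:
    """Procrustes superimposition of configuration y onto configuration x.

    ``D`` is the minimised sum of squared deviations after both
    configurations are normalised to unit total sum of squares, so
    ``D`` is in [0, 1] and ``t0 = sqrt(1 - D)``.  ``rotation``, ``scale``
    and ``translation`` map the second configuration onto the first in the
    original coordinates: ``y_fit = scale * y @ rotation + translation``.
    """

    D: float
    t0: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    p_value: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.D <= 1.0 + 1e-12:
            raise ValueError(f"D={self.D} outside [0, 1]")
        if abs(self.t0 - np.sqrt(max(0.0, 1.0 - self.D))) > 1e-12:
            raise ValueError("t0 != sqrt(1 - D)")


def pca_scores(x: np.ndarray, k: int = 2) -> np.ndarray:
    """Scores on the top-k principal components of a samples x features matrix.

    Columns are centred (not scaled); scores are ordered by decreasing
    variance with a deterministic sign convention — the largest-magnitude
    loading of each component is made positive.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise ValueError("constant matrix has no principal components")
    u, s, vt = linalg.svd(xc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _normalize(conf: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mu = conf.mean(axis=0)
    centred = conf - mu
    norm = float(np.sqrt((centred**2).sum()))
    if norm == 0.0:
        raise ValueError("degenerate configuration (zero total variance)")
    return centred / norm, mu, norm


def procrustes_fit(x: np.ndarray, y: np.ndarray) -> ProcrustesResult:
    """Optimal similarity transform of map ``y`` onto map ``x``.

    Both (n, 2) configurations are centred and scaled to unit total sum of
    squares; the rotation ranges over the full orthogonal group (so
    reflections are permitted, matching the sign-arbitrariness of PC
    axes).  ``D`` is the minimised residual sum of squares, ``t0`` the
    similarity score sqrt(1 - D).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("configurations must share the same (n, d) shape")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x0, mu_x, norm_x = _normalize(x)
    y0, mu_y, norm_y = _normalize(y)
    a = y0.T @ x0
    u, sv, vt = linalg.svd(a)
    rotation = u @ vt
    trace = float(sv.sum())
    d = max(0.0, 1.0 - trace**2)
    scale_norm = trace  # optimal scaling of the normalised y0
    scale = scale_norm * norm_x / norm_y
    translation = mu_x - scale * (mu_y @ rotation)
    return ProcrustesResult(
        D=min(d, 1.0),
        t0=float(np.sqrt(max(0.0, 1.0 - d))),
        rotation=rotation,
        scale=float(scale),
        translation=translation,
    )


def procrustes_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 100_000, seed=None
) -> ProcrustesResult:
    """Permutation test of Procrustes similarity.

    The null permutes the row order of ``y`` (the geographic locations)
    ``n_perm`` times; ``p = (1 + #{t0_perm >= t0_obs}) / (1 + n_perm)``.

    For 2-D configurations the permuted t0 has the closed form
    ``sqrt(||A||_F^2 + 2 |det A|)`` with ``A = y0_perm^T x0``, which lets
    all permutations be evaluated in one vectorised pass.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fit = procrustes_fit(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, _, _ = _normalize(x)
    y0, _, _ = _normalize(y)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 20_000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        yp = y0[perms]                       # (b, n, 2)
        a = np.einsum("bni,nj->bij", yp, x0)  # (b, 2, 2)
        frob2 = (a**2).sum(axis=(1, 2))
        det = a[:, 0, 0] * a[:, 1, 1] - a[:, 0, 1] * a[:, 1, 0]
        t0_perm = np.sqrt(frob2 + 2.0 * np.abs(det))
        count += int(np.sum(t0_perm >= fit.t0 - 1e-12))
        done += b
    p = (1 + count) / (1 + n_perm)
    return ProcrustesResult(
        D=fit.D,
        t0=fit.t0,
        rotation=fit.rotation,
        scale=fit.scale,
        translation=fit.translation,
        p_value=p,
        n_permutations=n_perm,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
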