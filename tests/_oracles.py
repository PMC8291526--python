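"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — double loops, full enumeration,
grid minimisation — and shares no code with the package's vectorised
paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def euclidean_double_loop(values: np.ndarray) -> np.ndarray:
    n, k = values.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for c in range(k):
                s += (values[i, c] - values[j, c]) ** 2
            out[i, j] = math.sqrt(s)
    return out


def hamming_pairwise_loop(values, mask, normalize=True):
    n, k = values.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            mism = joint = 0
            for c in range(k):
                if not mask[i, c] and not mask[j, c]:
                    joint += 1
                    if values[i, c] != values[j, c]:
                        mism += 1
            out[i, j] = mism / joint if normalize else mism
    return out


def pearson_naive(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def partial_corr_naive(x, y, z):
    rxy = pearson_naive(x, y)
    rxz = pearson_naive(x, z)
    ryz = pearson_naive(y, z)
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))


def _upper(values):
    n = values.shape[0]
    return np.array([values[i, j] for i in range(n) for j in range(i + 1, n)])


def mantel_exact(a_values, b_values, alternative="greater"):
    """Exact permutation p over all n! relabelings of b; returns (r, p)."""
    n = a_values.shape[0]
    va = _upper(a_values)
    r_obs = pearson_naive(va, _upper(b_values))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        bp = b_values[np.ix_(perm, perm)]
        r = pearson_naive(va, _upper(bp))
        total += 1
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += abs(r) >= abs(r_obs) - 1e-12
    return r_obs, count / total


def partial_mantel_exact(a_values, b_values, c_values, alternative="greater"):
    """Exact permutation p over all n! relabelings of a; returns (r, p)."""
    n = a_values.shape[0]
    vb, vc = _upper(b_values), _upper(c_values)
    r_obs = partial_corr_naive(_upper(a_values), vb, vc)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        ap = a_values[np.ix_(perm, perm)]
        r = partial_corr_naive(_upper(ap), vb, vc)
        total += 1
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += abs(r) >= abs(r_obs) - 1e-12
    return r_obs, count / total


def procrustes_d_grid(x, y, n_theta=20001):
    """Minimum normalised Procrustes D by dense search over rotation angle
    (both orientation classes) with the scale optimised per angle."""
    def norm(c):
        c = c - c.mean(axis=0)
        return c / math.sqrt((c**2).sum())

    x0, y0 = norm(np.asarray(x, float)), norm(np.asarray(y, float))
    best = np.inf
    thetas = np.linspace(0.0, 2.0 * math.pi, n_theta)
    for reflect in (False, True):
        yr = y0.copy()
        if reflect:
            yr[:, 1] = -yr[:, 1]
        for th in thetas:
            rot = np.array([[math.cos(th), -math.sin(th)],
                            [math.sin(th), math.cos(th)]])
            proj = float((x0 * (yr @ rot)).sum())  # optimal scale = proj
            d = 1.0 - proj * proj if proj > 0 else 1.0
            best = min(best, d)
    return best


def procrustes_t0_svd_free(x, y):
    return math.sqrt(max(0.0, 1.0 - procrustes_d_grid(x, y)))


def procrustes_exact_p(x, y):
    """Exact permutation p of the Procrustes t0 over all row orders of y."""
    def norm(c):
        c = c - c.mean(axis=0)
        return c / math.sqrt((c**2).sum())

    x0, y0 = norm(np.asarray(x, float)), norm(np.asarray(y, float))

    def t0_of(yp):
        a = yp.T @ x0
        sv = np.linalg.svd(a, compute_uv=False)
        return float(sv.sum())

    t_obs = t0_of(y0)
    n = x0.shape[0]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        count += t0_of(y0[list(perm)]) >= t_obs - 1e-12
    return t_obs, count / total


def t_pvalue_betainc(t, df, two_sided=True):
    """Student-t tail probability via the regularised incomplete beta."""
    from scipy.special import betainc

    p_two = betainc(df / 2.0, 0.5, df / (df + t * t))
    if two_sided:
        return p_two
    return p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
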