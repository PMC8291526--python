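"""Construction of the five distance matrices the analysis compares.

* Euclidean distance between haplogroup frequency compositions (paternal
  and maternal genetic distances);
* Hamming distance between binary trait vectors (lexical cognate sets,
  phoneme inventories), with pairwise-complete handling of missing cells;
* great-circle (orthodromic) geographic distance, optionally log10-scaled.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import (
    DistanceMatrix,
    FrequencyTable,
    PopulationPanel,
    TraitTable,
    align_ids,
)

__all__ = [
    "euclidean_distances",
    "hamming_distances",
    "geographic_distances",
    "haversine_km",
    "align_matrices",
    "EARTH_RADIUS_KM",
]

#: mean Earth radius used for great-circle distances
EARTH_RADIUS_KM = 6371.0


def euclidean_distances(freq: FrequencyTable) -> DistanceMatrix:
    """Euclidean distance between rows of a haplogroup frequency table.

    Entry (i, j) is ``sqrt(sum_k (f_ik - f_jk)^2)`` over haplogroup
    columns k.
    """
    if freq.n < 2:
        raise ValueError("need at least 2 populations")
    d = squareform(pdist(freq.values, metric="euclidean"))
    return DistanceMatrix(d, freq.ids, kind="euclidean")


def hamming_distances(
    traits: TraitTable,
    policy: str = "pairwise_complete",
    normalize: bool = True,
) -> DistanceMatrix:
    """Hamming distance between binary trait vectors.

    Entry (i, j) counts jointly observed traits on which languages i and j
    disagree.  Missing cells are handled per ``policy``:

    ``pairwise_complete``
        For each pair, ignore traits missing in either language (the
        cognate-set convention for patchy lexical data).  With
        ``normalize=True`` the count is divided by the number of jointly
        observed traits for that pair.
    ``complete_case``
        Drop every trait column containing any missing value, then compare
        on the surviving columns.

    Raises ``ValueError`` when a pair shares no observed trait
    (pairwise_complete) or no column survives (complete_case).
    """
    if policy not in ("pairwise_complete", "complete_case"):
        raise ValueError(f"unknown policy {policy!r}")
    x = traits.values.astype(np.float64)
    obs = (~traits.mask).astype(np.float64)
    if policy == "complete_case":
        keep = obs.all(axis=0)
        if not keep.any():
            raise ValueError("complete_case dropped all trait columns")
        x = x[:, keep]
        obs = obs[:, keep]
    x = x * obs  # zero out masked cells
    # joint observation counts and mismatch counts via matrix products:
    # mismatches(i,j) = sum over jointly observed k of x_ik xor x_jk
    n_joint = obs @ obs.T
    ones = x @ x.T                       # both present (1,1)
    xi_obs = x @ obs.T                   # i has 1 where both observed
    xj_obs = obs @ x.T                   # j has 1 where both observed
    mismatch = (xi_obs - ones) + (xj_obs - ones)
    off = ~np.eye(traits.n, dtype=bool)
    if np.any(n_joint[off] == 0):
        i, j = np.argwhere((n_joint == 0) & off)[0]
        raise ValueError(
            f"languages {traits.ids[i]!r} and {traits.ids[j]!r} share no "
            "jointly observed trait"
        )
    if normalize:
        d = np.divide(mismatch, n_joint, out=np.zeros_like(mismatch), where=n_joint > 0)
    else:
        d = mismatch
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, traits.ids, kind="hamming")


def haversine_km(coords: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from (n, 2) (lat, lon) degrees.

    Uses the haversine formulation on a sphere of radius
    ``EARTH_RADIUS_KM``, which is numerically stable at small separations.
    """
    coords = np.asarray(coords, dtype=float)
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def geographic_distances(
    panel: PopulationPanel,
    apply_log10: bool = True,
    floor_km: float = 1.0,
) -> DistanceMatrix:
    """Orthodromic distance matrix, optionally transformed to log10(d).

    When ``apply_log10`` is set, off-diagonal distances below ``floor_km``
    are floored first so the logarithm is defined for (nearly) co-located
    populations; the diagonal stays 0 by convention, which is harmless
    because Mantel-type statistics use off-diagonal entries only.
    """
    d = haversine_km(panel.coordinates())
    if apply_log10:
        if floor_km <= 0:
            raise ValueError("floor_km must be positive when apply_log10")
        off = ~np.eye(panel.n, dtype=bool)
        vals = np.maximum(d[off], floor_km)
        d[off] = np.log10(vals)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, panel.ids, kind="geographic")


def align_matrices(
    matrices: Sequence[DistanceMatrix], min_common: int = 3
) -> list[DistanceMatrix]:
    """Restrict all matrices to their sorted common id set, same order."""
    common = align_ids(matrices, min_common=min_common)
    return [m.filter(common) for m in matrices]
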