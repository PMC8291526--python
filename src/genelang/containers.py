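"""Core labelled data containers shared across the package.

The pipeline's lingua franca is :class:`DistanceMatrix` — a labelled,
symmetric, zero-diagonal pairwise matrix.  Input data arrive as a
:class:`PopulationPanel` (coordinates + group labels), two
:class:`FrequencyTable` objects (Y-chromosomal and mtDNA haplogroup
compositions) and two :class:`TraitTable` objects (binary lexical-cognate
and phoneme-inventory matrices with a missingness mask).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationPanel",
    "FrequencyTable",
    "TraitTable",
    "DistanceMatrix",
    "ResultRecord",
    "align_ids",
]

#: maximum tolerated asymmetry in a DistanceMatrix
_SYMMETRY_TOL = 1e-12


def _check_ids(ids: Sequence[str]) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids: {dupes}")
    return ids


@dataclass
class PopulationPanel:
    """Population labels, coordinates (decimal degrees) and group membership.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by unique population id, with columns ``latitude``,
        ``longitude``, ``group`` and optionally ``language_group``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"latitude", "longitude", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        _check_ids(self.table.index)
        lat = self.table["latitude"].to_numpy(float)
        lon = self.table["longitude"].to_numpy(float)
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude outside [-180, 180]")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def n(self) -> int:
        return len(self.table)

    def coordinates(self) -> np.ndarray:
        """Return an (n, 2) array of (latitude, longitude)."""
        return self.table[["latitude", "longitude"]].to_numpy(float)

    def group_ids(self, group: str) -> list[str]:
        mask = self.table["group"] == group
        return [str(i) for i in self.table.index[mask]]

    def subset(self, ids: Sequence[str]) -> "PopulationPanel":
        return PopulationPanel(self.table.loc[list(ids)])


@dataclass
class FrequencyTable:
    """Population x haplogroup compositional matrix; rows sum to 1.

    ``lineage`` records whether the table describes the paternal
    (Y-chromosomal) or maternal (mtDNA) side.
    """

    ids: list[str]
    haplogroups: list[str]
    values: np.ndarray
    lineage: str = "paternal"
    renormalized: bool = False

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.haplogroups)):
            raise ValueError("frequency table shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("negative frequency entry")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("rows do not sum to 1 within 1e-9")
        if self.lineage not in ("paternal", "maternal"):
            raise ValueError(f"unknown lineage {self.lineage!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.haplogroups)

    def subset(self, ids: Sequence[str]) -> "FrequencyTable":
        idx = [self.ids.index(i) for i in ids]
        return FrequencyTable(
            list(ids), list(self.haplogroups), self.values[idx], self.lineage,
            self.renormalized,
        )


@dataclass
class TraitTable:
    """Language x binary-trait matrix with an explicit missingness mask.

    ``values`` is 0/1 wherever ``mask`` is False; masked cells carry no
    information (their stored value is arbitrary and forced to 0).
    ``system`` is ``"lexical"`` (cognate-set presence) or ``"phonemic"``
    (phoneme-inventory presence).
    """

    ids: list[str]
    traits: list[str]
    values: np.ndarray
    mask: np.ndarray
    system: str = "lexical"

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids)
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (len(self.ids), len(self.traits))
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValueError("trait table shape mismatch")
        observed = self.values[~self.mask]
        if not np.isin(observed, (0, 1)).all():
            raise ValueError("non-binary observed trait value")
        vals = np.where(self.mask, 0, self.values).astype(np.int8)
        self.values = vals
        if self.system not in ("lexical", "phonemic"):
            raise ValueError(f"unknown trait system {self.system!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self, missing_code: str = "?") -> pd.DataFrame:
        out = self.values.astype(object)
        out[self.mask] = missing_code
        return pd.DataFrame(out, index=self.ids, columns=self.traits)

    def subset(self, ids: Sequence[str]) -> "TraitTable":
        idx = [self.ids.index(i) for i in ids]
        return TraitTable(
            list(ids), list(self.traits), self.values[idx], self.mask[idx],
            self.system,
        )


class DistanceMatrix:
    """Labelled symmetric pairwise-distance matrix.

    Parameters
    ----------
    values : (n, n) array_like
        Symmetric with zero diagonal.  Off-diagonal entries must be
        non-negative except for ``kind="residual"`` (regression residuals)
        and ``kind="geographic"`` after a log10 transform.
    ids : sequence of str
        Unique row/column labels.
    kind : str
        One of ``euclidean``, ``hamming``, ``geographic``, ``residual``,
        ``generic``.
    """

    KINDS = ("euclidean", "hamming", "geographic", "residual", "generic")

    def __init__(self, values, ids: Sequence[str], kind: str = "generic"):
        values = np.array(values, dtype=float)
        ids = _check_ids(ids)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {values.shape}")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetry {asym:g} exceeds {_SYMMETRY_TOL:g}")
        if np.abs(np.diagonal(values)).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("diagonal is not zero")
        if kind not in self.KINDS:
            raise ValueError(f"unknown kind {kind!r}")
        if kind in ("euclidean", "hamming") and np.any(values < 0):
            raise ValueError(f"negative entries invalid for kind={kind!r}")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.ids = ids
        self.kind = kind
        self._index = {p: i for i, p in enumerate(ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DistanceMatrix kind={self.kind!r} n={self.n}>"

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (length n(n-1)/2)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def filter(self, ids: Sequence[str]) -> "DistanceMatrix":
        """Restrict to ``ids`` in the given order."""
        try:
            idx = [self._index[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"id not in matrix: {exc.args[0]!r}") from None
        return DistanceMatrix(self.values[np.ix_(idx, idx)], ids, self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "generic") -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(df.to_numpy(float), list(df.index), kind)

    @classmethod
    def from_condensed(cls, vec, ids: Sequence[str], kind: str = "generic") -> "DistanceMatrix":
        from scipy.spatial.distance import squareform

        return cls(squareform(np.asarray(vec, float)), ids, kind)


def align_ids(objects: Sequence, min_common: int = 3) -> list[str]:
    """Sorted intersection of the ``ids`` of labelled objects.

    Raises ``ValueError`` when fewer than ``min_common`` ids are shared —
    downstream permutation tests are meaningless below 3 populations.
    """
    sets = [set(o.ids) for o in objects]
    common = set.intersection(*sets) if sets else set()
    if len(common) < min_common:
        raise ValueError(
            f"only {len(common)} shared ids; need at least {min_common}"
        )
    return sorted(common)


@dataclass
class ResultRecord:
    """One row of pipeline output: a single matrix-association test."""

    test_name: str
    matrix_a: str
    matrix_b: str
    control: Optional[str]
    method: str
    statistic: float
    p_value: Optional[float]
    n_permutations: int
    n: int
    seed: Optional[int]
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        extra = d.pop("extra")
        d.update(extra)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
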