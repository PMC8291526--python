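"""Jackknife-style subsampling schemes for robustness of partial Mantel tests.

Two subsampling designs probe whether the gene-language conclusions
depend on the imbalance between the two population groups (here the
Indo-Iranian vs European split of an Indo-European panel):

* **Scheme I** (balanced): keep every population of the focal group and
  draw an equal-sized random subset of the remaining populations.
* **Scheme II** (unconstrained): draw a random subset of the requested
  size from all populations.

Each replicate restricts all five distance matrices to the drawn subset
and re-runs the four gene-language partial Mantel tests controlling
geography; replicates are aggregated into summary statistics over r and p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, PopulationPanel
from .mantel import partial_mantel

__all__ = [
    "JackknifeSummary",
    "resample_scheme1",
    "resample_scheme2",
    "run_jackknife",
    "summarize_audit",
    "DEFAULT_TESTS",
]

#: the four gene-language tests, as (focal a, focal b) distance-matrix keys
DEFAULT_TESTS = (
    ("Y", "lexicon"),
    ("Y", "phoneme"),
    ("mtDNA", "lexicon"),
    ("mtDNA", "phoneme"),
)


@dataclass
class JackknifeSummary:
    """Aggregate of one partial Mantel test over jackknife replicates."""

    test: str
    scheme: str
    replicates: int
    r_median: float
    r_min: float
    r_max: float
    r_ci_low: float
    r_ci_high: float
    p_q25: float
    p_q50: float
    p_q75: float
    count_p_lt_05: int
    count_p_lt_01: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (
            self.r_min - 1e-12
            <= self.r_ci_low
            <= self.r_median + 1e-12
            and self.r_median - 1e-12
            <= self.r_ci_high
            <= self.r_max + 1e-12
        ):
            raise ValueError("summary ordering violated")
        if max(self.count_p_lt_05, self.count_p_lt_01) > self.replicates:
            raise ValueError("counts exceed replicates")


def resample_scheme1(
    panel: PopulationPanel, focal_group: str, rng
) -> list[str]:
    """All focal-group ids plus an equal-sized random complement sample.

    With g focal populations the subset has size 2g; errors if the
    complement is smaller than the focal group.
    """
    rng = np.random.default_rng(rng)
    focal = panel.group_ids(focal_group)
    g = len(focal)
    if g < 2:
        raise ValueError(f"focal group {focal_group!r} has fewer than 2 populations")
    complement = [i for i in panel.ids if i not in set(focal)]
    if len(complement) < g:
        raise ValueError(
            f"complement ({len(complement)}) smaller than focal group ({g})"
        )
    drawn = list(rng.choice(complement, size=g, replace=False))
    return focal + drawn


def resample_scheme2(panel: PopulationPanel, size: int, rng) -> list[str]:
    """Uniform without-replacement sample of ``size`` populations."""
    rng = np.random.default_rng(rng)
    if not 3 <= size <= panel.n:
        raise ValueError(f"size {size} out of range [3, {panel.n}]")
    return list(rng.choice(panel.ids, size=size, replace=False))


def _replicate_rng(seed: Optional[int], replicate: int) -> np.random.Generator:
    # deterministic per-replicate stream so any single replicate can be
    # reproduced in isolation
    ss = np.random.SeedSequence(entropy=0 if seed is None else seed,
                                spawn_key=(replicate,))
    return np.random.default_rng(ss)


def run_jackknife(
    matrices: dict[str, DistanceMatrix],
    panel: PopulationPanel,
    scheme: str,
    replicates: int = 500,
    tests: Sequence[tuple[str, str]] = DEFAULT_TESTS,
    control: str = "geography",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    focal_group: Optional[str] = None,
    size: Optional[int] = None,
    alternative: str = "greater",
) -> tuple[list[JackknifeSummary], pd.DataFrame]:
    """Run a jackknife scheme and aggregate the partial Mantel results.

    Parameters
    ----------
    matrices : dict
        Aligned distance matrices keyed by the labels used in ``tests``
        plus the ``control`` key (default ``"geography"``).
    scheme : {"I", "II"}
        Scheme I requires ``focal_group``; scheme II requires ``size``.
    replicates : int
        Number of subsampled data sets (study default 500).
    n_perm : int
        Permutations per partial Mantel test (study default 10 000; a few
        hundred suffice for desk-scale checks).

    Returns
    -------
    (summaries, audit)
        One :class:`JackknifeSummary` per test, plus a long-format audit
        table with one row per replicate x test from which the summaries
        recompute exactly.
    """
    if scheme not in ("I", "II"):
        raise ValueError("scheme must be 'I' or 'II'")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    needed = {control} | {k for pair in tests for k in pair}
    missing = needed - set(matrices)
    if missing:
        raise KeyError(f"missing distance matrices: {sorted(missing)}")
    ids0 = matrices[control].ids
    for key in needed:
        if matrices[key].ids != ids0:
            raise ValueError("matrices not aligned; use align_matrices first")
    if scheme == "I":
        if focal_group is None:
            raise ValueError("scheme I requires focal_group")
    elif size is None:
        raise ValueError("scheme II requires size")

    rows = []
    for rep in range(replicates):
        rng = _replicate_rng(seed, rep)
        if scheme == "I":
            subset = resample_scheme1(panel, focal_group, rng)
        else:
            subset = resample_scheme2(panel, size, rng)
        subset = sorted(subset)
        if len(subset) < 4:
            raise ValueError("subset too small for a partial test (n < 4)")
        sub = {k: matrices[k].filter(subset) for k in needed}
        for a_key, b_key in tests:
            res = partial_mantel(
                sub[a_key], sub[b_key], sub[control],
                n_perm=n_perm, alternative=alternative, seed=rng,
            )
            rows.append(
                {
                    "replicate": rep,
                    "scheme": scheme,
                    "test": f"{a_key}-{b_key}",
                    "n": len(subset),
                    "r": res.r,
                    "p_value": res.p_value,
                    "subset": ";".join(subset),
                }
            )
    audit = pd.DataFrame(rows)
    summaries = summarize_audit(audit, seed=seed)
    return summaries, audit


def summarize_audit(
    audit: pd.DataFrame, seed: Optional[int] = None
) -> list[JackknifeSummary]:
    """Aggregate a per-replicate audit table into one summary per test.

    Quantiles use the linear-interpolation convention of numpy's default
    percentile; the 95% interval is the (2.5%, 97.5%) percentile interval
    over replicates.
    """
    summaries = []
    for (scheme, test), grp in audit.groupby(["scheme", "test"], sort=True):
        r = grp["r"].to_numpy(float)
        p = grp["p_value"].to_numpy(float)
        lo, hi = np.percentile(r, [2.5, 97.5])
        summaries.append(
            JackknifeSummary(
                test=test,
                scheme=scheme,
                replicates=len(grp),
                r_median=float(np.median(r)),
                r_min=float(r.min()),
                r_max=float(r.max()),
                r_ci_low=float(lo),
                r_ci_high=float(hi),
                p_q25=float(np.quantile(p, 0.25)),
                p_q50=float(np.quantile(p, 0.50)),
                p_q75=float(np.quantile(p, 0.75)),
                count_p_lt_05=int(np.sum(p < 0.05)),
                count_p_lt_01=int(np.sum(p < 0.01)),
                seed=seed,
            )
        )
    return summaries
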