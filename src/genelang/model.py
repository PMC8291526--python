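"""Top-level model/results interface for the gene-language test grid.

:class:`CoevolutionAnalysis` is built from the five inputs (paternal and
maternal haplogroup frequencies, lexical and phonemic trait tables,
population coordinates), or from a synthetic configuration, and its
:meth:`~CoevolutionAnalysis.fit` runs the full association grid:

* plain Mantel tests between every pair of the four gene/language
  distance matrices (6 tests) and between each of them and geography (4);
* partial tests of the 6 gene/language pairs controlling for geographic
  distance, for each requested partial method.

``fit`` returns a :class:`CoevolutionResults` carrying one
:class:`~genelang.containers.ResultRecord` per test, a ``summary()``
table, and writers for delimited/JSON output.
"""

from __future__ import annotations

import logging
import time
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as glio
from .containers import DistanceMatrix, PopulationPanel, ResultRecord
from .distances import (
    align_matrices,
    euclidean_distances,
    geographic_distances,
    hamming_distances,
)
from .mantel import mantel, partial_mantel, partial_pearson, residual_mantel

logger = logging.getLogger("genelang")

__all__ = ["CoevolutionAnalysis", "CoevolutionResults", "run_pipeline"]

#: the four focal distance matrices, in grid order
FOCAL = ("Y", "mtDNA", "lexicon", "phoneme")

_PARTIAL_METHODS = ("partial_mantel", "residual_mantel", "partial_pearson")


class CoevolutionAnalysis:
    """Gene-language coevolution test grid for one population panel.

    Parameters
    ----------
    panel : PopulationPanel
        Population coordinates and group labels.
    freq_y, freq_mt : FrequencyTable or None
        Paternal / maternal haplogroup compositions.
    lexicon, phonemes : TraitTable or None
        Binary trait tables.  Any of the four data tables may be omitted;
        the grid then runs on the available subset (with a warning).
    apply_log10 : bool
        log10-transform the geographic distances (the analysis default).
    hamming_policy, hamming_normalize
        Missing-data policy and normalisation for trait distances.
    """

    def __init__(
        self,
        panel: PopulationPanel,
        freq_y=None,
        freq_mt=None,
        lexicon=None,
        phonemes=None,
        *,
        apply_log10: bool = True,
        floor_km: float = 1.0,
        hamming_policy: str = "pairwise_complete",
        hamming_normalize: bool = True,
    ):
        if panel.n < 3:
            raise ValueError("need at least 3 populations")
        self.panel = panel
        self.tables = {
            "Y": freq_y, "mtDNA": freq_mt,
            "lexicon": lexicon, "phoneme": phonemes,
        }
        if all(v is None for v in self.tables.values()):
            raise ValueError("no data tables supplied")
        self.apply_log10 = apply_log10
        self.floor_km = floor_km
        self.hamming_policy = hamming_policy
        self.hamming_normalize = hamming_normalize
        self._distances: Optional[dict[str, DistanceMatrix]] = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_files(
        cls, panel_path, freq_y_path=None, freq_mt_path=None,
        lexicon_path=None, phonemes_path=None, missing_code: str = "?",
        delimiter: Optional[str] = None, **kwargs,
    ) -> "CoevolutionAnalysis":
        panel = glio.read_population_panel(panel_path, delimiter)
        fy = (glio.read_frequency_table(freq_y_path, delimiter, "paternal")
              if freq_y_path else None)
        fm = (glio.read_frequency_table(freq_mt_path, delimiter, "maternal")
              if freq_mt_path else None)
        lex = (glio.read_trait_table(lexicon_path, missing_code, delimiter,
                                     "lexical") if lexicon_path else None)
        phon = (glio.read_trait_table(phonemes_path, missing_code, delimiter,
                                      "phonemic") if phonemes_path else None)
        return cls(panel, fy, fm, lex, phon, **kwargs)

    @classmethod
    def from_synthetic(cls, cfg=None, seed: Optional[int] = None, **kwargs):
        from .simulate import SyntheticConfig, generate_dataset

        cfg = cfg if cfg is not None else SyntheticConfig()
        ds = generate_dataset(cfg, seed=seed)
        return cls(ds.panel, ds.freq_y, ds.freq_mt, ds.lexicon, ds.phonemes,
                   **kwargs)

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "CoevolutionAnalysis":
        return cls(dataset.panel, dataset.freq_y, dataset.freq_mt,
                   dataset.lexicon, dataset.phonemes, **kwargs)

    # -- distances --------------------------------------------------------
    def distance_matrices(self) -> dict[str, DistanceMatrix]:
        """Aligned distance matrices for every available table + geography."""
        if self._distances is not None:
            return self._distances
        mats: dict[str, DistanceMatrix] = {}
        for key in ("Y", "mtDNA"):
            if self.tables[key] is not None:
                mats[key] = euclidean_distances(self.tables[key])
        for key in ("lexicon", "phoneme"):
            if self.tables[key] is not None:
                mats[key] = hamming_distances(
                    self.tables[key], self.hamming_policy,
                    self.hamming_normalize,
                )
        mats["geography"] = geographic_distances(
            self.panel, self.apply_log10, self.floor_km
        )
        keys = list(mats)
        aligned = align_matrices([mats[k] for k in keys])
        self._distances = dict(zip(keys, aligned))
        return self._distances

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        partial_methods: Sequence[str] = ("partial_mantel",),
        n_perm: int = 10_000,
        alternative: str = "greater",
        seed: Optional[int] = 0,
        include_pearson: bool = False,
    ) -> "CoevolutionResults":
        """Run the Mantel grid and the partial grid controlling geography.

        Each test draws its permutations from a stream derived
        deterministically from ``seed`` and the test's position in the
        grid, so the full result set is reproducible and individual tests
        are re-runnable in isolation.
        """
        unknown = set(partial_methods) - set(_PARTIAL_METHODS)
        if unknown:
            raise ValueError(f"unknown partial methods: {sorted(unknown)}")
        mats = self.distance_matrices()
        present = [k for k in FOCAL if k in mats]
        absent = [k for k in FOCAL if k not in mats]
        if absent:
            warnings.warn(
                f"tables missing for {absent}; running the reduced grid",
                UserWarning, stacklevel=2,
            )
        records: list[ResultRecord] = []
        counter = 0

        def stream(offset: int):
            if seed is None:
                return None
            return np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(offset,))
            )

        pairs = [(a, b) for i, a in enumerate(present)
                 for b in present[i + 1:]]
        for a, b in pairs:
            records.append(self._run(mantel, "mantel", a, b, None, mats,
                                     n_perm, alternative, seed, stream(counter)))
            counter += 1
        for a in present:
            records.append(self._run(mantel, "mantel", a, "geography", None,
                                     mats, n_perm, alternative, seed,
                                     stream(counter)))
            counter += 1
        methods = list(partial_methods)
        if include_pearson and "partial_pearson" not in methods:
            methods.append("partial_pearson")
        for method in methods:
            for a, b in pairs:
                if method == "partial_pearson":
                    t0 = time.perf_counter()
                    res = partial_pearson(mats[a], mats[b], mats["geography"])
                    records.append(_to_record(res, a, b, "geography", seed))
                    _log(records[-1], time.perf_counter() - t0)
                else:
                    func = partial_mantel if method == "partial_mantel" else residual_mantel
                    records.append(self._run(func, method, a, b, "geography",
                                             mats, n_perm, alternative, seed,
                                             stream(counter)))
                    counter += 1
        return CoevolutionResults(self, records)

    def _run(self, func, method, a, b, control, mats, n_perm, alternative,
             seed, rng) -> ResultRecord:
        args = (mats[a], mats[b]) if control is None else (
            mats[a], mats[b], mats[control])
        t0 = time.perf_counter()
        res = func(*args, n_perm=n_perm, alternative=alternative, seed=rng)
        rec = _to_record(res, a, b, control, seed, method)
        _log(rec, time.perf_counter() - t0)
        return rec


def _to_record(res, a, b, control, seed, method=None) -> ResultRecord:
    method = method or res.method
    name = f"{a}~{b}" + (f"|{control}" if control else "")
    return ResultRecord(
        test_name=f"{method}:{name}",
        matrix_a=a, matrix_b=b, control=control, method=method,
        statistic=res.r, p_value=res.p_value,
        n_permutations=res.n_permutations, n=res.n, seed=seed,
        extra={"alternative": res.alternative, "note": res.note},
    )


def _log(rec: ResultRecord, wall: float) -> None:
    logger.info(
        "test=%s method=%s n=%d statistic=%.6f p=%s seed=%s wall=%.3fs",
        rec.test_name, rec.method, rec.n, rec.statistic,
        "NA" if rec.p_value is None else f"{rec.p_value:.6g}",
        rec.seed, wall,
    )


class CoevolutionResults:
    """Result set of one fitted gene-language grid."""

    def __init__(self, model: CoevolutionAnalysis, records: list[ResultRecord]):
        self.model = model
        self.records = records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.records])

    def get(self, method: str, a: str, b: str) -> ResultRecord:
        for r in self.records:
            if r.method == method and {r.matrix_a, r.matrix_b} == {a, b}:
                return r
        raise KeyError(f"no record for {method} {a}~{b}")

    def summary(self) -> str:
        """Plain-text summary table of the fitted grid."""
        df = self.to_frame()
        lines = ["Gene-language coevolution test grid",
                 f"populations: {self.records[0].n}",
                 "=" * 78,
                 f"{'test':<38}{'r':>10}{'p':>12}{'perms':>10}"]
        for _, row in df.iterrows():
            p = "NA" if pd.isna(row["p_value"]) else f"{row['p_value']:.4g}"
            lines.append(
                f"{row['test_name']:<38}{row['statistic']:>10.4f}{p:>12}"
                f"{int(row['n_permutations']):>10}"
            )
        lines.append("=" * 78)
        return "\n".join(lines)

    def save(self, directory, stem: str = "results") -> None:
        directory = Path(directory)
        glio.write_results(self.records, directory / f"{stem}.tsv",
                           directory / f"{stem}.json")


def run_pipeline(config: dict, out_dir=None) -> CoevolutionResults:
    """Config-driven entry point.

    ``config`` keys: either ``synthetic`` (a dict of SyntheticConfig
    overrides plus optional ``seed``) or ``inputs`` (paths ``panel``,
    ``freq_y``, ``freq_mt``, ``lexicon``, ``phonemes``); optional ``fit``
    overrides (``partial_methods``, ``n_perm``, ``alternative``, ``seed``,
    ``include_pearson``) and ``missing_code``.
    """
    if "synthetic" in config:
        from .simulate import SyntheticConfig

        syn = dict(config["synthetic"])
        seed = syn.pop("seed", 0)
        model = CoevolutionAnalysis.from_synthetic(SyntheticConfig(**syn),
                                                   seed=seed)
    elif "inputs" in config:
        paths = config["inputs"]
        model = CoevolutionAnalysis.from_files(
            paths["panel"],
            paths.get("freq_y"), paths.get("freq_mt"),
            paths.get("lexicon"), paths.get("phonemes"),
            missing_code=config.get("missing_code", "?"),
        )
    else:
        raise ValueError("config needs a 'synthetic' or 'inputs' section")
    fit_kwargs = dict(config.get("fit", {}))
    results = model.fit(**fit_kwargs)
    if out_dir is not None:
        results.save(out_dir)
    return results
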