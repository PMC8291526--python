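"""Reading and writing the pipeline's tabular formats.

Canonical on-disk format is delimited text (tab by default, comma
accepted) with the id in the first column.  Distance matrices additionally
serialize as NEXUS ``TAXA`` + ``DISTANCES`` blocks so split networks
(Neighbour-Nets) can be built externally in SplitsTree; a minimal NEXUS
distances reader is bundled for round-trip validation.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    DistanceMatrix,
    FrequencyTable,
    PopulationPanel,
    ResultRecord,
    TraitTable,
)

__all__ = [
    "read_frequency_table",
    "read_trait_table",
    "read_population_panel",
    "read_distance_matrix",
    "write_table",
    "write_distance_matrix",
    "write_nexus_distances",
    "read_nexus_distances",
    "write_results",
    "write_dataset",
]

#: maximum tolerated deviation of a frequency row sum from 1 before error
ROW_SUM_TOL = 1e-6


def _read_delimited(path, delimiter: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else None
    # sep=None lets pandas sniff tab vs comma
    return pd.read_csv(path, sep=sep, engine="python", index_col=0,
                       dtype={0: str})


def read_frequency_table(
    path, delimiter: Optional[str] = None, lineage: str = "paternal"
) -> FrequencyTable:
    """Load a population x haplogroup frequency table.

    Rows whose sum deviates from 1 by at most ``ROW_SUM_TOL`` are
    renormalized (and the table flagged); larger deviations are hard
    errors — they usually mean a malformed composition.
    """
    df = _read_delimited(path, delimiter)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative frequency entry")
    sums = values.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_SUM_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"{path}: row {df.index[i]!r} sum {sums[i]:.6g} outside tolerance "
            f"{ROW_SUM_TOL:g} of 1"
        )
    renorm = bool(np.any(sums != 1.0))
    values = values / sums[:, None]
    return FrequencyTable(
        list(df.index.astype(str)), list(df.columns.astype(str)), values,
        lineage=lineage, renormalized=renorm,
    )


def read_trait_table(
    path, missing_code: str = "?", delimiter: Optional[str] = None,
    system: str = "lexical",
) -> TraitTable:
    """Load a language x binary-trait table with a missing-value code."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else None
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0, dtype=str)
    raw = df.to_numpy(dtype=object)
    raw = np.char.strip(raw.astype(str))
    mask = raw == missing_code
    values = np.zeros(raw.shape, dtype=np.int8)
    for token, val in (("0", 0), ("1", 1)):
        values[raw == token] = val
    bad = ~(mask | (raw == "0") | (raw == "1"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary cell {raw[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return TraitTable(
        list(df.index.astype(str)), list(df.columns.astype(str)),
        values, mask, system=system,
    )


def read_population_panel(path, delimiter: Optional[str] = None) -> PopulationPanel:
    """Load a panel of population ids, coordinates and group labels."""
    df = _read_delimited(path, delimiter)
    df.index = df.index.astype(str)
    return PopulationPanel(df)


def read_distance_matrix(
    path, delimiter: Optional[str] = None, kind: str = "generic"
) -> DistanceMatrix:
    df = _read_delimited(path, delimiter)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_dataframe(df, kind=kind)


def write_table(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, float_format="%.10g")


def write_distance_matrix(d: DistanceMatrix, path, delimiter: str = "\t") -> None:
    write_table(d.to_dataframe(), path, delimiter)


# ---------------------------------------------------------------------------
# NEXUS DISTANCES interchange

def _nexus_label(label: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus_distances(d: DistanceMatrix, path) -> None:
    """Write TAXA + DISTANCES blocks (triangle=both) readable by SplitsTree."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={d.n};",
             "  TAXLABELS"]
    for label in d.ids:
        lines.append(f"    {_nexus_label(label)}")
    lines += ["  ;", "END;", "", "BEGIN DISTANCES;",
              f"  DIMENSIONS NTAX={d.n};",
              "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
              "  MATRIX"]
    for i, label in enumerate(d.ids):
        row = " ".join(f"{v:.6f}" for v in d.values[i])
        lines.append(f"    {_nexus_label(label)} {row}")
    lines += ["  ;", "END;", ""]
    path.write_text("\n".join(lines))


def _nexus_tokens(text: str) -> list[str]:
    # quoted labels may contain spaces; '' is an escaped quote
    tokens = []
    for m in re.finditer(r"'((?:[^']|'')*)'|(\S+)", text):
        if m.group(1) is not None:
            tokens.append(m.group(1).replace("''", "'"))
        else:
            tokens.append(m.group(2))
    return tokens


def read_nexus_distances(path) -> DistanceMatrix:
    """Minimal reader for the DISTANCES block this package writes.

    Understands TRIANGLE=BOTH with labels and diagonal — enough for
    round-trip validation; it is not a general NEXUS parser.
    """
    text = Path(path).read_text()
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError(f"{path}: not a NEXUS file")
    m = re.search(r"BEGIN\s+DISTANCES\s*;(.*?)END\s*;", text,
                  re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError(f"{path}: no DISTANCES block")
    block = m.group(1)
    ntax_m = re.search(r"NTAX\s*=\s*(\d+)", block, re.IGNORECASE)
    if not ntax_m:
        raise ValueError(f"{path}: DISTANCES block lacks NTAX")
    ntax = int(ntax_m.group(1))
    mat_m = re.search(r"MATRIX(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mat_m:
        raise ValueError(f"{path}: DISTANCES block lacks MATRIX")
    tokens = _nexus_tokens(mat_m.group(1))
    if len(tokens) != ntax * (ntax + 1):
        raise ValueError(f"{path}: expected {ntax * (ntax + 1)} matrix tokens, "
                         f"got {len(tokens)}")
    ids, rows = [], []
    for i in range(ntax):
        chunk = tokens[i * (ntax + 1): (i + 1) * (ntax + 1)]
        ids.append(chunk[0])
        rows.append([float(v) for v in chunk[1:]])
    values = np.array(rows)
    # symmetrize away printed-precision noise
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids, kind="generic")


# ---------------------------------------------------------------------------
# results and dataset output

def write_results(records: Sequence[ResultRecord], path_tsv, path_json=None) -> None:
    """Write ResultRecords as a delimited table and, optionally, JSON."""
    df = pd.DataFrame([r.to_dict() for r in records])
    write_table(df.set_index("test_name"), path_tsv)
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps([r.to_dict() for r in records], indent=2, sort_keys=True)
        )


def write_dataset(dataset, directory) -> dict[str, Path]:
    """Write a SyntheticDataset's five tables plus a truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": directory / "panel.tsv",
        "freq_y": directory / "freq_y.tsv",
        "freq_mt": directory / "freq_mt.tsv",
        "lexicon": directory / "lexicon.tsv",
        "phonemes": directory / "phonemes.tsv",
        "truth": directory / "truth.json",
    }
    write_table(dataset.panel.table, paths["panel"])
    write_table(dataset.freq_y.to_dataframe(), paths["freq_y"])
    write_table(dataset.freq_mt.to_dataframe(), paths["freq_mt"])
    write_table(dataset.lexicon.to_dataframe(), paths["lexicon"])
    write_table(dataset.phonemes.to_dataframe(), paths["phonemes"])
    truth = dict(dataset.truth)
    for key in ("d_geo_km", "d_paternal", "d_maternal"):
        if key in truth:
            truth[key] = truth[key].to_dataframe().to_dict()
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True,
                                         default=str))
    return paths
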