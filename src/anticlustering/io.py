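"""Readers and writers for feature tables, distance matrices and partitions.

Conventions: CSV/TSV with a header row (delimiter sniffed, overridable);
an optional leading object-ID column; partition files are two-column TSV
(object_id, cluster) with 1-based cluster labels. Distance matrices are
validated for symmetry to 1e-8 and then symmetrized by averaging.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import DissimilarityMatrix
from .pareto import ParetoSet
from .partition import Partition

__all__ = [
    "read_feature_table",
    "read_distance_matrix",
    "read_words",
    "read_pairs",
    "read_partition",
    "write_partition",
    "write_outputs",
]


def _read_table(path, delimiter=None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else None
    return pd.read_csv(path, sep=sep, engine="python")


def read_feature_table(path, *, id_col: bool = False, delimiter=None):
    """Numeric N x P feature table; returns (values, object_ids)."""
    df = _read_table(path, delimiter)
    if id_col:
        ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    else:
        ids = [str(i + 1) for i in range(len(df))]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate object IDs")
    for r, c in zip(*np.where(df.isna() | ~df.map(np.isreal))):
        raise ValueError(
            f"{path}: non-numeric cell at row {r + 1}, column {df.columns[c]!r}"
        )
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite cell at row {r + 1}, column {df.columns[c]!r}"
        )
    return values, ids


def read_distance_matrix(path, *, id_col: bool = False, delimiter=None) -> DissimilarityMatrix:
    """Square symmetric matrix; validated then symmetrized by averaging."""
    df = _read_table(path, delimiter)
    ids: list[str] = []
    if id_col:
        ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: distance matrix must be square, got {values.shape}")
    if np.abs(np.diag(values)).max() > 1e-8:
        raise ValueError(f"{path}: distance matrix diagonal must be zero")
    if not np.allclose(values, values.T, rtol=0, atol=1e-8):
        raise ValueError(f"{path}: matrix asymmetric beyond 1e-8 tolerance")
    if (values < -1e-8).any():
        raise ValueError(f"{path}: raw dissimilarities must be non-negative")
    values = np.clip((values + values.T) / 2.0, 0.0, None)
    return DissimilarityMatrix(values, object_ids=ids)


def read_words(path) -> list[str]:
    """One word per line; blank lines ignored."""
    words = [w.strip() for w in Path(path).read_text().splitlines()]
    return [w for w in words if w]


def read_pairs(path, object_ids: list[str]):
    """Two-column TSV of object IDs -> list of 0-based index pairs."""
    index = {oid: i for i, oid in enumerate(object_ids)}
    pairs = []
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    for _, row in df.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        if a not in index or b not in index:
            raise ValueError(f"{path}: unknown object ID in pair ({a}, {b})")
        pairs.append((index[a], index[b]))
    return pairs


def write_partition(part: Partition, object_ids: list[str], path) -> None:
    """Two-column TSV, clusters 1-based, canonical labels."""
    canon = part.canonical()
    with open(path, "w") as fh:
        fh.write("object_id\tcluster\n")
        for oid, k in zip(object_ids, canon):
            fh.write(f"{oid}\t{k + 1}\n")


def read_partition(path, object_ids: list[str]) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    order = {oid: i for i, oid in enumerate(object_ids)}
    assign = np.empty(len(object_ids), dtype=np.int64)
    for _, row in df.iterrows():
        assign[order[str(row.iloc[0])]] = int(row.iloc[1]) - 1
    return Partition(assign)


def write_outputs(pareto: ParetoSet, object_ids: list[str], config: dict, outdir) -> Path:
    """Partition TSV per Pareto entry plus a JSON summary and run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not len(pareto):
        raise RuntimeError("empty Pareto set: internal error")
    summary = []
    entries = sorted(pareto, key=lambda e: -e.dispersion)
    for rank, entry in enumerate(entries, start=1):
        fname = f"partition_{rank}.tsv"
        write_partition(entry.partition, object_ids, outdir / fname)
        summary.append(
            {
                "diversity": float(f"{entry.diversity:.17g}"),
                "dispersion": entry.dispersion
                if np.isfinite(entry.dispersion)
                else "inf",
                "partition_file": fname,
            }
        )
    (outdir / "pareto.json").write_text(json.dumps(summary, indent=2) + "\n")
    (outdir / "run_config.json").write_text(json.dumps(config, indent=2) + "\n")
    return outdir / "pareto.json"
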