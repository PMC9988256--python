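"""Readers and writers for the plain-text interchange formats.

Counts and expression matrices travel as TSV with genes as rows (first
column the gene identifier); sample metadata as TSV with columns
``sample, individual, muscle, batch``; gene sets (cell-type markers,
pathways) as GMT; object tables from segmented histology images as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in count matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in count matrix")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = {"sample", "individual", "muscle"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    return meta.set_index("sample", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_object_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "area_um2" in df.columns and (df["area_um2"] <= 0).any():
        raise ValueError("object areas must be positive")
    return df


def write_object_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return {c: x[c].tolist() for c in x.columns}
    if isinstance(x, pd.Series):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
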