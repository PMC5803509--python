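"""Readers and writers for the package's plain-text file formats.

All tabular formats are tab-separated text; floating-point values are written
at 12 significant digits so that report tables round-trip across platforms.
Gene-set collections use the GMT convention (term, description, members...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.12g"

ATLAS_COLUMNS = ["roi_id", "name", "hemisphere", "node_class", "x", "y", "z"]


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.loc[:, ATLAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    missing = set(ATLAS_COLUMNS) - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    return atlas


def write_adjacency(weights: pd.DataFrame, path: str | Path) -> None:
    """Square symmetric adjacency matrix; header and index are ROI names."""
    weights.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_adjacency(path: str | Path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t", index_col=0)
    if list(w.index) != list(w.columns):
        raise ValueError(f"{path}: adjacency row and column labels differ")
    return w


def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gmt(sets: dict[str, set[str] | list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, members in sets.items():
            desc = descriptions.get(term, term)
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            term, desc, *members = fields
            sets[term] = set(members)
            descriptions[term] = desc
    return sets, descriptions


def write_foldchange(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, ["gene", "log2fc"]].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_foldchange(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "log2fc"} <= set(table.columns):
        raise ValueError("fold-change table must have columns: gene, log2fc")
    return table


def write_gene_list(genes: list[str], path: str | Path, name: str = "gene") -> None:
    pd.DataFrame({name: list(genes)}).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    table = pd.read_csv(path, sep="\t")
    return table.iloc[:, 0].astype(str).tolist()


def _jsonify(obj):
    if isinstance(obj, pd.Series):
        return {"index": list(map(str, obj.index)), "values": obj.to_numpy().tolist()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=1, sort_keys=True)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
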