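"""Readers and writers for the plain-text formats used throughout.

Expression matrices, trait tables, probe annotations and module
assignments travel as tab-separated text with explicit headers; gene set
collections use the GMT convention (one term per line: name, description,
then member gene ids). All functions round-trip losslessly with their
``write_*`` counterparts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


# ---------------------------------------------------------------- expression

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    First column holds row ids (probes or gene symbols), header holds
    sample ids. Duplicated row or column ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dup[:10]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# -------------------------------------------------------------------- traits

def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a samples x traits table from TSV (samples in rows)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------- annotation

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation table (probe, symbol[, name]) from TSV.

    Missing symbols become empty strings, which mark unannotated probes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate probe ids in {path}")
    if df.shape[1] < 1:
        raise ValueError("annotation needs at least a symbol column")
    df = df.iloc[:, :2].copy()
    df.columns = ["symbol", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = ""
    df["symbol"] = df["symbol"].fillna("")
    df["name"] = df["name"].fillna("")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe")


# --------------------------------------------------------------- assignments

def read_assignment(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df.iloc[:, 0].rename("module")


def write_assignment(assignment: pd.Series, path: str | Path) -> None:
    assignment.rename("module").to_csv(path, sep="\t", index_label="gene")


# ----------------------------------------------------------------- gene sets

@dataclasses.dataclass
class GeneSetCollection:
    """A named collection of gene sets with one-line descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {term}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate members in gene set: {term}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def description(self, term: str) -> str:
        return self.descriptions.get(term, "")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in collection.items():
            desc = collection.description(term)
            fh.write("\t".join([term, desc, *genes]) + "\n")


# -------------------------------------------------------------------- json

def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_jsonl(records: Iterable[Mapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True, default=_json_default))
            fh.write("\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
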