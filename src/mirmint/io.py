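"""Tabular readers and writers for every on-disk format the pipeline touches.

The canonical tabular dialect is TSV: tab-delimited, UTF-8, one header row,
``.`` as the decimal separator.  Readers validate the schema strictly and
raise :class:`~mirmint.errors.SchemaError` naming the file (and line, where
a specific row is at fault); they never silently coerce or drop rows.

Formats
-------
expression TSV   feature id column ("feature") + one numeric column per sample
sample map TSV   columns (sample, group)
Ct TSV           columns (sample, target, ct[, efficiency])
curves TSV       columns (well, cycle, fluorescence)
prediction TSV   columns (mirna, gene, algorithm, validated in {0,1})
GMT              gene-set collection: set id, description, tab-separated members
SIF / GraphML    network interchange (writers live on RegulatoryNetwork)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

FEATURE_COL = "feature"


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"unreadable TSV: {exc}", path=path) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing}; found {list(df.columns)}", path=path)
    return df


def _to_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & (out[col] != "")
        empty = out[col] == ""
        problem = bad | empty
        if problem.any():
            # +2: header row and 1-based numbering
            line = int(np.flatnonzero(problem.to_numpy())[0]) + 2
            raise SchemaError(f"non-numeric value {out[col][problem].iloc[0]!r} in column {col!r}", path=path, line=line)
        out[col] = converted
    return out


# ---------------------------------------------------------------- expression

def write_expression(df: pd.DataFrame, path) -> None:
    """Write a features x samples matrix; the index holds feature ids."""
    out = df.copy()
    out.index.name = FEATURE_COL
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_expression(path) -> pd.DataFrame:
    df = _read_tsv(path, [FEATURE_COL])
    sample_cols = [c for c in df.columns if c != FEATURE_COL]
    if not sample_cols:
        raise SchemaError("expression table has no sample columns", path=path)
    if df[FEATURE_COL].duplicated().any():
        dup = df[FEATURE_COL][df[FEATURE_COL].duplicated()].iloc[0]
        raise SchemaError(f"duplicated feature id {dup!r}", path=path)
    df = _to_numeric(df, sample_cols, path)
    return df.set_index(FEATURE_COL)


# ---------------------------------------------------------------- sample map

def write_sample_map(groups: pd.Series, path) -> None:
    """``groups`` maps sample id -> group label."""
    frame = pd.DataFrame({"sample": groups.index, "group": groups.to_numpy()})
    frame.to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.Series:
    df = _read_tsv(path, ["sample", "group"])
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise SchemaError(f"duplicated sample id {dup!r}", path=path)
    if (df["group"] == "").any():
        line = int(np.flatnonzero((df["group"] == "").to_numpy())[0]) + 2
        raise SchemaError("empty group label", path=path, line=line)
    return pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy(), name="group")


# ------------------------------------------------------------------- Ct TSV

def write_ct(df: pd.DataFrame, path) -> None:
    cols = ["sample", "target", "ct"] + (["efficiency"] if "efficiency" in df.columns else [])
    df.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ct(path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "target", "ct"])
    numeric = ["ct"] + (["efficiency"] if "efficiency" in df.columns else [])
    df = _to_numeric(df, numeric, path)
    return df


# ------------------------------------------------------------------- curves

def write_curves(df: pd.DataFrame, path) -> None:
    df.loc[:, ["well", "cycle", "fluorescence"]].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_curves(path) -> pd.DataFrame:
    df = _read_tsv(path, ["well", "cycle", "fluorescence"])
    df = _to_numeric(df, ["cycle", "fluorescence"], path)
    df["cycle"] = df["cycle"].astype(int)
    return df


# -------------------------------------------------------------- predictions

def write_predictions(df: pd.DataFrame, path) -> None:
    out = df.loc[:, ["mirna", "gene", "algorithm", "validated"]].copy()
    out["validated"] = out["validated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = _read_tsv(path, ["mirna", "gene", "algorithm", "validated"])
    df = _to_numeric(df, ["validated"], path)
    bad = ~df["validated"].isin([0, 1])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError("validated flag must be 0 or 1", path=path, line=line)
    df["validated"] = df["validated"].astype(bool)
    return df


# ---------------------------------------------------------------------- GMT

def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    """``sets`` maps term id -> (description, member ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError("GMT row needs id, description and >= 1 member", path=path, line=i)
            term, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if term in sets:
                raise SchemaError(f"duplicated set id {term!r}", path=path, line=i)
            if not members:
                raise SchemaError("empty member list", path=path, line=i)
            sets[term] = (desc, members)
    return sets


# ------------------------------------------------------------ id lists, JSON

def write_id_list(ids, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for x in ids:
            fh.write(f"{x}\n")


def read_id_list(path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=path)
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
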