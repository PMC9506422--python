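"""Readers and writers for the plain-text interchange formats.

Intensity matrices are TSV with proteins as rows and measurement ids as
columns; an empty cell means missing. Gene set collections use the GMT
convention (name, description, then members, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import IntensityMatrix


def read_intensity_tsv(path, scale: str = "linear", stage: str = "raw") -> IntensityMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return IntensityMatrix(values=values.astype(float), scale=scale, stage=stage)


def write_intensity_tsv(m: IntensityMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def write_mask_tsv(m: IntensityMatrix, path) -> None:
    m.mask().to_csv(path, sep="\t", index_label="protein_id")


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("bio_rep", "tech_rep", "batch"):
        if col in ann.columns:
            ann[col] = ann[col].astype(str)
    return ann


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        members = [g for g in fields[2:] if g]
        if not members:
            raise ValueError(f"gene set {name!r} has no members")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature(path) -> dict:
    """Marker signature from JSON ({name, positive_set, negative_set}) or TSV
    (columns: marker, set with values positive/negative)."""
    path = Path(path)
    if path.suffix == ".json":
        sig = json.loads(path.read_text())
        for key in ("name", "positive_set", "negative_set"):
            if key not in sig:
                raise ValueError(f"signature file lacks {key!r}")
        return sig
    df = pd.read_csv(path, sep="\t")
    if not {"marker", "set"} <= set(df.columns):
        raise ValueError("signature TSV needs columns: marker, set")
    return {
        "name": path.stem,
        "positive_set": df.loc[df["set"] == "positive", "marker"].tolist(),
        "negative_set": df.loc[df["set"] == "negative", "marker"].tolist(),
    }


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_membership_tsv(path) -> pd.DataFrame:
    """Database membership table: protein_id, database_id, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"protein_id", "database_id", "category"}
    if not need <= set(df.columns):
        raise ValueError(f"membership TSV needs columns {sorted(need)}")
    return df


def read_drug_tsv(path) -> pd.DataFrame:
    """Drug sensitivity table: cell_line, drug, ln_ic50."""
    df = pd.read_csv(path, sep="\t")
    need = {"cell_line", "drug", "ln_ic50"}
    if not need <= set(df.columns):
        raise ValueError(f"drug TSV needs columns {sorted(need)}")
    return df
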