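"""Database-overlap annotation (secreted / surface / plasma / druggable) and
protein-abundance vs drug-sensitivity correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: category -> minimum number of member databases for a positive call
DEFAULT_MIN_DB = {
    "secretome": 2,
    "surfaceome": 2,
    "plasma": 1,
    "plasma-actively-secreted": 1,
    "druggable": 1,
}


def annotate_overlap(
    membership: pd.DataFrame, category: str, min_db: int | None = None
) -> set[str]:
    """Proteins listed in at least ``min_db`` databases of the category.

    ``membership`` is long-format: protein_id, database_id, category.
    """
    cats = set(membership["category"])
    if category not in cats:
        raise ValueError(f"unknown category {category!r}; have {sorted(cats)}")
    sub = membership[membership["category"] == category].drop_duplicates(
        ["protein_id", "database_id"]
    )
    n_db = sub["database_id"].nunique()
    if min_db is None:
        min_db = DEFAULT_MIN_DB.get(category, 1)
    if min_db > n_db:
        raise ValueError(f"min_db={min_db} exceeds {n_db} database(s) in {category!r}")
    counts = sub.groupby("protein_id")["database_id"].nunique()
    return set(counts.index[counts >= min_db])


def drug_correlation(
    abundance: pd.Series, drugs: pd.DataFrame, drug: str
) -> tuple[float, float, int]:
    """Pearson r and two-sided p between a protein's abundance and ln(IC50)
    of one drug over the intersecting cell lines.

    Returns (r, p, n); (nan, nan, n) flagged when either vector is constant.
    """
    sub = drugs[drugs["drug"] == drug].dropna(subset=["ln_ic50"])
    merged = pd.DataFrame({"abund": abundance}).join(
        sub.set_index("cell_line")["ln_ic50"], how="inner"
    ).dropna()
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 overlapping cell lines, have {n}")
    if merged["abund"].std(ddof=1) == 0 or merged["ln_ic50"].std(ddof=1) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(merged["abund"], merged["ln_ic50"])
    return float(r), float(p), n


def subtype_drug_summary(drugs: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-drug median ln(IC50) per subtype plus the subtype rank (1 = lowest
    median). Subtypes without measured lines are reported missing."""
    sub_map = ann.set_index("cell_line")["subtype"]
    d = drugs.dropna(subset=["ln_ic50"]).copy()
    d["subtype"] = d["cell_line"].map(sub_map)
    d = d.dropna(subset=["subtype"])
    med = d.pivot_table(index="drug", columns="subtype", values="ln_ic50", aggfunc="median")
    med = med.reindex(columns=sorted(ann["subtype"].unique()))
    ranks = med.rank(axis=1, method="min")
    med.columns = [f"median_{c}" for c in med.columns]
    ranks.columns = [f"rank_{c}" for c in ranks.columns]
    return pd.concat([med, ranks], axis=1)
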