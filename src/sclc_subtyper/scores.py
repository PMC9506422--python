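"""Per-sample marker-signature scores (NE, EMT) and their association.

Score = mean across-sample Z of the positive markers minus mean Z of the
negative markers; for the NE score positives are the neuroendocrine markers,
for the EMT score positives are the mesenchymal markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntensityMatrix


@dataclass(frozen=True)
class MarkerSignature:
    name: str
    positive_set: frozenset[str]
    negative_set: frozenset[str]

    def __post_init__(self):
        if not self.positive_set or not self.negative_set:
            raise ValueError(f"signature {self.name!r}: empty marker set")
        if self.positive_set & self.negative_set:
            raise ValueError(f"signature {self.name!r}: overlapping marker sets")

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerSignature":
        return cls(
            name=d["name"],
            positive_set=frozenset(d["positive_set"]),
            negative_set=frozenset(d["negative_set"]),
        )


@dataclass
class ScoreTable:
    name: str
    scores: pd.Series  # sample -> score
    n_positive_used: int
    n_negative_used: int
    dropped_constant: tuple[str, ...] = ()


def _mean_z(m: IntensityMatrix, markers: frozenset[str], label: str):
    sub = m.values.loc[m.values.index.intersection(list(markers))]
    if sub.empty:
        raise ValueError(f"no quantified marker from the {label} set")
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    kept = sub.loc[~constant]
    if kept.empty:
        raise ValueError(f"all quantified {label} markers are constant")
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[~constant], axis=0)
    return z.mean(axis=0), int(kept.shape[0]), tuple(sub.index[constant])


def signature_score(m: IntensityMatrix, sig: MarkerSignature) -> ScoreTable:
    """Mean Z of quantified positive markers minus mean Z of negatives.

    Z-scoring is per protein across samples with the n-1 SD convention;
    markers with zero across-sample SD are dropped and reported.
    """
    pos, n_pos, drop_p = _mean_z(m, sig.positive_set, "positive")
    neg, n_neg, drop_n = _mean_z(m, sig.negative_set, "negative")
    return ScoreTable(
        name=sig.name,
        scores=pos - neg,
        n_positive_used=n_pos,
        n_negative_used=n_neg,
        dropped_constant=drop_p + drop_n,
    )


def score_association(a: ScoreTable, b: ScoreTable) -> tuple[float, float]:
    """Pearson correlation between two score tables with two-sided t-test p."""
    if set(a.scores.index) != set(b.scores.index):
        raise ValueError("score tables cover different samples")
    x = a.scores
    y = b.scores.loc[x.index]
    if len(x) < 3:
        raise ValueError("need >= 3 samples for correlation")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in a score table")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def score_table_frame(tables: list[ScoreTable]) -> pd.DataFrame:
    """Wide table: one row per sample, one column per signature."""
    df = pd.DataFrame({t.name: t.scores for t in tables})
    df.index.name = "sample"
    return df
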