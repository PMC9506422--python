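"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SUBTYPES = ("A", "N", "P", "Y")
CULTURE_TYPES = ("adherent", "semi-adherent", "suspension")

#: cell states in the mask
OBSERVED = "observed"
IMPUTED = "imputed"
MISSING = "missing"


@dataclass
class IntensityMatrix:
    """Protein-by-sample intensity matrix with explicit missingness provenance.

    ``values`` holds intensities (NaN where missing), ``imputed`` flags cells
    whose value was filled in by imputation rather than measured. ``scale``
    is ``"linear"`` or ``"log2"``; ``stage`` tracks the processing stage.
    """

    values: pd.DataFrame
    scale: str = "linear"
    stage: str = "raw"
    imputed: pd.DataFrame | None = None
    uncorrected: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate measurement ids: {dups[:5]}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def observed_mask(self) -> pd.DataFrame:
        """True where a value was actually measured (present, not imputed)."""
        return self.values.notna() & ~self.imputed

    def mask(self) -> pd.DataFrame:
        """Per-cell state: observed / imputed / missing."""
        out = pd.DataFrame(MISSING, index=self.values.index, columns=self.values.columns)
        out[self.values.notna()] = OBSERVED
        out[self.imputed] = IMPUTED
        return out

    def with_values(self, values: pd.DataFrame, **kw) -> "IntensityMatrix":
        imputed = kw.pop("imputed", None)
        if imputed is None:
            imputed = self.imputed.reindex(
                index=values.index, columns=values.columns, fill_value=False
            )
        return replace(self, values=values, imputed=imputed, **kw)

    def copy(self) -> "IntensityMatrix":
        return replace(self, values=self.values.copy(), imputed=self.imputed.copy())


ANNOTATION_COLUMNS = (
    "measurement_id",
    "cell_line",
    "subtype",
    "batch",
    "culture_type",
    "bio_rep",
    "tech_rep",
)


def validate_annotation(ann: pd.DataFrame, level: str = "measurement") -> pd.DataFrame:
    """Validate a sample annotation table.

    ``level="measurement"`` requires the full replicate structure;
    ``level="cell_line"`` requires one row per cell line.
    """
    required = (
        list(ANNOTATION_COLUMNS) if level == "measurement" else ["cell_line", "subtype"]
    )
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    bad = set(ann["subtype"]) - set(SUBTYPES)
    if bad:
        raise ValueError(f"unknown subtype token(s): {sorted(bad)}")
    if "culture_type" in ann.columns:
        bad = set(ann["culture_type"]) - set(CULTURE_TYPES)
        if bad:
            raise ValueError(f"unknown culture type token(s): {sorted(bad)}")
    key = "measurement_id" if level == "measurement" else "cell_line"
    if ann[key].duplicated().any():
        raise ValueError(f"duplicate {key} in annotation")
    return ann


def annotation_for_columns(ann: pd.DataFrame, columns, key: str = "measurement_id"):
    """Subset and order annotation rows to match matrix columns."""
    ann = ann.set_index(key, drop=False)
    absent = [c for c in columns if c not in ann.index]
    if absent:
        raise ValueError(f"columns missing from annotation: {absent[:5]}")
    return ann.loc[list(columns)]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from a master seed."""
    import hashlib

    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))
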