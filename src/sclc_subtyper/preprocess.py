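"""Post-processing of label-free intensity matrices.

Stages: log2 transform + median normalization, per-vial technical-replicate
median, batch-effect regression, replicate averaging, valid-value filtering,
left-censored normal imputation, and on/off protein detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SUBTYPES, IntensityMatrix, annotation_for_columns


def log2_median_normalize(raw: IntensityMatrix) -> IntensityMatrix:
    """log2-transform and centre every measurement on the global median.

    The global median is the median of all observed log2 values before any
    shifting; each column is then shifted so its median equals it. Scale
    invariant: multiplying a raw column by a constant does not change its
    normalized values.
    """
    if raw.scale != "linear":
        raise ValueError("expected a raw linear-scale matrix")
    vals = raw.values
    nonpos = vals.le(0)
    if nonpos.any().any():
        loc = np.argwhere(nonpos.to_numpy())[0]
        raise ValueError(
            "non-positive intensity at protein "
            f"{vals.index[loc[0]]!r}, column {vals.columns[loc[1]]!r}"
        )
    log2v = np.log2(vals)
    global_median = float(np.nanmedian(log2v.to_numpy()))
    shifted = log2v - log2v.median(axis=0) + global_median
    return raw.with_values(shifted, scale="log2", stage="normalized")


def vial_median(m: IntensityMatrix, ann: pd.DataFrame) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Median over technical repeats from the same vial (cell line, bio
    replicate, batch), ignoring missing values."""
    for col in ("cell_line", "bio_rep", "batch", "tech_rep"):
        if col not in ann.columns:
            raise ValueError(f"annotation lacks replicate column {col!r}")
    cols = annotation_for_columns(ann, m.samples)
    key = cols["cell_line"] + "_b" + cols["bio_rep"].astype(str)
    agg = m.values.T.groupby(key.values, sort=False).median().T
    vial_ann = (
        cols.assign(measurement_id=key.values)
        .drop_duplicates("measurement_id")
        .loc[:, ["measurement_id", "cell_line", "subtype", "batch", "culture_type", "bio_rep"]]
        .reset_index(drop=True)
    )
    agg = agg.loc[:, vial_ann["measurement_id"].tolist()]
    return m.with_values(agg, stage="aggregated"), vial_ann


def replicate_mean(m: IntensityMatrix, ann: pd.DataFrame) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Arithmetic mean over remaining replicates of the same cell line,
    ignoring missing values; one column per cell line."""
    cols = annotation_for_columns(ann, m.samples)
    agg = m.values.T.groupby(cols["cell_line"].values, sort=False).mean().T
    line_ann = (
        cols.drop_duplicates("cell_line")
        .loc[:, [c for c in ("cell_line", "subtype", "culture_type") if c in cols.columns]]
        .reset_index(drop=True)
    )
    agg = agg.loc[:, line_ann["cell_line"].tolist()]
    out = m.with_values(agg, stage="aggregated")
    out.uncorrected = m.uncorrected
    return out, line_ann


def aggregate_replicates(m: IntensityMatrix, ann: pd.DataFrame) -> IntensityMatrix:
    """Per-vial median then per-cell-line mean; a cell is missing only when
    every contributing measurement was missing."""
    vm, vial_ann = vial_median(m, ann)
    out, _ = replicate_mean(vm, vial_ann)
    return out


def filter_valid(m: IntensityMatrix, min_frac: float = 0.8) -> IntensityMatrix:
    """Keep proteins observed in at least ``min_frac`` of samples."""
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    frac = m.values.notna().sum(axis=1) / m.values.shape[1]
    keep = (frac >= min_frac) & (frac > 0)
    out = m.with_values(m.values.loc[keep])
    out.stage = "filtered"
    return out


def correct_batch(m: IntensityMatrix, ann: pd.DataFrame) -> IntensityMatrix:
    """Remove additive batch differences by univariate linear regression.

    Per protein observed in every batch, the fit of intensity on the batch
    indicator is replaced by residual + grand mean of its observed values
    (equivalently: de-meaning each batch and restoring the grand mean).
    Proteins with no quantitative value in some batch are left unchanged and
    flagged in ``uncorrected``. Missing cells remain missing.
    """
    cols = annotation_for_columns(ann, m.samples)
    batches = cols["batch"]
    counts = batches.value_counts()
    if (counts == 0).any():
        raise ValueError("batch with zero samples")
    if counts.size < 2:
        return m.copy()

    vals = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    out = vals.copy()
    batch_codes, batch_ids = pd.factorize(batches.values)
    nb = len(batch_ids)
    onehot = np.equal.outer(batch_codes, np.arange(nb)).astype(float)  # samples x batches

    obs_per_batch = obs.astype(float) @ onehot  # proteins x batches
    correctable = (obs_per_batch > 0).all(axis=1)

    with np.errstate(invalid="ignore"):
        sums = np.where(obs, vals, 0.0) @ onehot
        batch_means = np.divide(
            sums, obs_per_batch, out=np.zeros_like(sums), where=obs_per_batch > 0
        )
        grand_mean = np.nansum(np.where(obs, vals, np.nan), axis=1) / obs.sum(axis=1)
    fitted = batch_means[:, batch_codes]
    corrected = vals - fitted + grand_mean[:, None]
    out[correctable] = corrected[correctable]
    out[~obs] = np.nan

    res = m.with_values(pd.DataFrame(out, index=m.proteins, columns=m.samples))
    res.stage = "corrected"
    res.uncorrected = frozenset(m.proteins[~correctable])
    return res


def impute_normal(
    m: IntensityMatrix, width: float = 0.3, downshift: float = 1.8, seed: int = 0
) -> IntensityMatrix:
    """Impute missing cells from a down-shifted normal per sample column.

    For a column with observed mean mu and SD sigma, missing cells are drawn
    independently from Normal(mu - downshift*sigma, (width*sigma)^2),
    mimicking left-censored low-abundance signal. Imputed cells are flagged.
    """
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy(dtype=float).copy()
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=0)
    if (n_obs < 2).any():
        bad = m.samples[n_obs < 2].tolist()
        raise ValueError(f"column(s) with <2 observed values: {bad[:5]}")
    imputed_flag = np.zeros_like(obs)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        mu = col[~miss].mean()
        sigma = col[~miss].std(ddof=1)
        col[miss] = rng.normal(mu - downshift * sigma, width * sigma, size=miss.sum())
        imputed_flag[miss, j] = True
    out = m.with_values(
        pd.DataFrame(vals, index=m.proteins, columns=m.samples),
        imputed=pd.DataFrame(
            m.imputed.to_numpy() | imputed_flag, index=m.proteins, columns=m.samples
        ),
    )
    out.stage = "imputed"
    return out


@dataclass(frozen=True)
class OnOffCall:
    protein: str
    subtype: str
    direction: str  # "on" | "off"
    fractions: tuple[tuple[str, float], ...]  # per-subtype presence fractions


def detect_on_off(
    m: IntensityMatrix,
    ann: pd.DataFrame,
    hi: float = 0.85,
    lo: float = 0.15,
    sample_key: str = "cell_line",
) -> list[OnOffCall]:
    """Call proteins present in >= hi of one subtype's samples and <= lo of
    each other subtype's ('on'), or the converse ('off').

    Presence means an observed (pre-imputation) value.
    """
    cols = ann.set_index(sample_key).loc[list(m.samples)]
    subtype = cols["subtype"]
    groups = {s: m.samples[(subtype == s).values] for s in SUBTYPES}
    empty = [s for s, g in groups.items() if len(g) == 0]
    if empty:
        raise ValueError(f"empty subtype(s): {empty}")
    present = m.observed_mask()
    frac = pd.DataFrame(
        {s: present[g].sum(axis=1) / len(g) for s, g in groups.items()}
    )
    calls: list[OnOffCall] = []
    for protein, row in frac.iterrows():
        for s in SUBTYPES:
            others = [t for t in SUBTYPES if t != s]
            fr = tuple((t, float(row[t])) for t in SUBTYPES)
            if row[s] >= hi and all(row[t] <= lo for t in others):
                calls.append(OnOffCall(str(protein), s, "on", fr))
            elif row[s] <= lo and all(row[t] >= hi for t in others):
                calls.append(OnOffCall(str(protein), s, "off", fr))
    return calls
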