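"""Gene-set analyses: overrepresentation (ORA), pre-ranked GSEA with a
weighted running-sum statistic, the subtype-characteristic filter, the
cross-omics concordance rule, and single-sample GSEA (area under the running
enrichment score) with min-max scaling."""

from __future__ import annotations

from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# ORA

def ora(hits: set, universe: set, gs: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric upper-tail overrepresentation test per gene set.

    Sets are intersected with the universe first; sets disjoint from the
    universe are excluded. p = P[X >= overlap]. BH across tested sets.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M, n_hits = len(universe), len(hits)
    rows = []
    for name, members in gs.items():
        in_univ = set(members) & universe
        if not in_univ:
            continue
        overlap = len(in_univ & hits)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(in_univ), n_hits))
        rows.append({"gene_set": name, "set_size": len(in_univ), "overlap": overlap, "p": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    if len(out):
        out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# pre-ranked GSEA

def running_sum_es(scores: np.ndarray, hit: np.ndarray, weight: float = 1.0):
    """Straightforward O(N) weighted KS running sum; returns (ES, RES).

    Hits increment proportionally to |score|^weight, misses decrement
    uniformly; ES is the signed maximum deviation of the running sum.
    """
    scores = np.asarray(scores, dtype=float)
    hit = np.asarray(hit, dtype=bool)
    m = int(hit.sum())
    N = len(scores)
    if m == 0 or m == N:
        raise ValueError("set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = hit.astype(float)
        total = float(m)
    steps = np.where(hit, w_hit / total, -1.0 / (N - m))
    res = np.cumsum(steps)
    es = res[np.argmax(np.abs(res))]
    return float(es), res


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, N: int) -> np.ndarray:
    """Batch ES for hit-position sets (B x m, sorted ascending).

    The running sum attains its extrema immediately after a hit or just
    before one, so only 2m candidate values per set are evaluated.
    """
    pos = np.asarray(pos)
    B, m = pos.shape
    w = absw[pos]  # B x m
    W = w.sum(axis=1, keepdims=True)
    zero = (W == 0).ravel()
    if zero.any():
        w[zero] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / W
    k = np.arange(1, m + 1)
    miss = 1.0 / (N - m)
    after = cumw - (pos + 1 - k) * miss
    before = np.concatenate([np.zeros((B, 1)), cumw[:, :-1]], axis=1) - (pos - (k - 1)) * miss
    # interleave in walk order so exact-|value| ties resolve to the first
    # extremum encountered, matching a step-by-step running sum
    cand = np.empty((B, 2 * m))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    # rounding makes exact rational ties (k/(N-m)) insensitive to the float
    # summation path; argmax then takes the first extremum in walk order
    key = np.round(np.abs(cand), 12)
    return np.take_along_axis(cand, np.argmax(key, axis=1)[:, None], axis=1).ravel()


def prerank_gsea(
    ranked: pd.Series,
    gs: dict[str, list[str]],
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranked``: score per protein, sorted descending (re-sorted defensively
    with protein-id tie-break). Null ES distributions are shared between sets
    of equal size. ``exhaustive=True`` enumerates every hit-position
    combination instead of sampling (small instances only). NES = ES divided
    by the mean |null ES| of matching sign; nominal p is the same-sign tail
    fraction; BH across sets.
    """
    ranked = pd.Series(ranked).astype(float)
    if not np.all(np.isfinite(ranked.values)):
        raise ValueError("ranking scores must be finite")
    names_all = ranked.index.to_numpy().astype(str)
    sc = ranked.to_numpy()
    order_idx = np.lexsort((names_all, -sc))  # descending score, id tie-break
    names = names_all[order_idx]
    scores = sc[order_idx]
    N = len(names)
    pos_of = {g: i for i, g in enumerate(names)}
    absw = np.abs(scores) ** weight

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(m: int) -> np.ndarray:
        if m not in null_cache:
            if exhaustive:
                combos = np.array(list(_combinations(range(N), m)), dtype=int)
                null_cache[m] = _es_from_positions(combos, absw, N)
            else:
                r = rng.random((nperm, N))
                pos = np.sort(np.argpartition(r, m, axis=1)[:, :m], axis=1)
                null_cache[m] = _es_from_positions(pos, absw, N)
        return null_cache[m]

    rows, excluded = [], []
    for name, members in gs.items():
        pos = np.array(sorted(pos_of[g] for g in set(members) if g in pos_of))
        m = len(pos)
        if m < min_size:
            excluded.append((name, f"overlap {m} < {min_size}"))
            continue
        if m == N:
            excluded.append((name, "covers entire ranking"))
            continue
        es = _es_from_positions(pos[None, :], absw, N)[0]
        null = null_es(m)
        same = null > 0 if es > 0 else (null < 0 if es < 0 else np.ones_like(null, bool))
        n_same = int(same.sum())
        if es == 0 or n_same == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / np.abs(null[same]).mean()
            p = max(int((np.abs(null[same]) >= abs(es)).sum()), 1) / n_same
        rows.append({"gene_set": name, "ES": es, "NES": nes, "p": p, "n_overlap": m})
    out = pd.DataFrame(rows).set_index("gene_set") if rows else pd.DataFrame(
        columns=["ES", "NES", "p", "n_overlap"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# subtype-characteristic filter and cross-omics concordance

def subtype_characteristic(
    results: dict[str, pd.DataFrame], p_thr: float = 0.01, n_comparisons: int = 3
) -> pd.DataFrame:
    """Gene sets with p < p_thr in every comparison of a subtype against the
    others and an unequivocal NES sign; returns direction ('up'/'down')."""
    if len(results) != n_comparisons:
        raise ValueError(
            f"expected {n_comparisons} comparisons, got {len(results)}: {sorted(results)}"
        )
    frames = list(results.values())
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    rows = []
    for name in common:
        ps = [f.loc[name, "p"] for f in frames]
        signs = {np.sign(f.loc[name, "NES"]) for f in frames}
        if all(p < p_thr for p in ps) and len(signs) == 1 and 0 not in signs:
            rows.append({"gene_set": name, "direction": "up" if signs == {1.0} else "down"})
    out = pd.DataFrame(rows, columns=["gene_set", "direction"])
    return out.set_index("gene_set")


def _supported_by(
    results: dict[str, pd.DataFrame], name: str, direction: str, p_other: float
) -> bool:
    sign = 1.0 if direction == "up" else -1.0
    for f in results.values():
        if name not in f.index:
            return False
        if not (f.loc[name, "p"] < p_other and np.sign(f.loc[name, "NES"]) == sign):
            return False
    return True


def cross_omics_concordance(
    prot_results: dict[str, pd.DataFrame],
    rna_results: dict[str, pd.DataFrame],
    prot_characteristic: pd.DataFrame,
    rna_characteristic: pd.DataFrame,
    subtype: str,
    p_other: float = 0.1,
) -> pd.DataFrame:
    """Support classification of characteristic gene sets across omics.

    A set characteristic in one dataset is 'both' when the other dataset has
    p < p_other in all relevant comparisons with matching NES sign (or is
    itself characteristic there with the same direction); otherwise it is
    supported by one dataset only.
    """
    calls: dict[str, dict] = {}
    for name, row in prot_characteristic.iterrows():
        d = row["direction"]
        in_rna = name in rna_characteristic.index and rna_characteristic.loc[name, "direction"] == d
        both = in_rna or _supported_by(rna_results, name, d, p_other)
        calls[name] = {
            "gene_set": name,
            "subtype": subtype,
            "direction": d,
            "support": "both" if both else "proteomics-only",
        }
    for name, row in rna_characteristic.iterrows():
        if name in calls:
            continue
        d = row["direction"]
        both = _supported_by(prot_results, name, d, p_other)
        calls[name] = {
            "gene_set": name,
            "subtype": subtype,
            "direction": d,
            "support": "both" if both else "transcriptomics-only",
        }
    out = pd.DataFrame(
        list(calls.values()), columns=["gene_set", "subtype", "direction", "support"]
    )
    return out.set_index("gene_set")


# ---------------------------------------------------------------------------
# ssGSEA

def ssgsea_sample_es(values: np.ndarray, hit: np.ndarray, weight: float = 0.75) -> float:
    """Area under the running enrichment score for one sample.

    ``values``: per-gene statistic already transformed (z-scored normalized
    ranks); genes are walked in decreasing order of value.
    """
    order = np.argsort(-values, kind="mergesort")
    h = hit[order]
    w = np.abs(values[order]) ** weight
    m = int(h.sum())
    N = len(values)
    wh = np.where(h, w, 0.0)
    total = wh.sum()
    if total == 0:
        wh = h.astype(float)
        total = float(m)
    steps = np.where(h, wh / total, -1.0 / (N - m))
    return float(np.cumsum(steps).sum())


def ssgsea(
    expr: pd.DataFrame,
    gs: dict[str, list[str]],
    weight: float = 0.75,
    min_overlap: int = 5,
    nperm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-sample GSEA on a gene x sample abundance matrix.

    Per sample, genes are rank-normalized and z-scored; the per-set statistic
    is the area under the weighted running enrichment score. NES divides the
    area by the mean |null area| of matching sign from gene-label
    permutations (shared per set size and sample). Returns (NES matrix,
    per-set min-max scaled matrix in [0, 1]).
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative (abundance-like)")
    rng = np.random.default_rng(seed)
    genes = expr.index.to_numpy()
    N = len(genes)
    kept = {}
    skipped = []
    gene_set = set(genes)
    for name, members in gs.items():
        overlap = [g for g in dict.fromkeys(members) if g in gene_set]
        if len(overlap) < min_overlap:
            skipped.append((name, f"overlap {len(overlap)} < {min_overlap}"))
            continue
        kept[name] = np.isin(genes, overlap)
    nes = pd.DataFrame(index=list(kept), columns=expr.columns, dtype=float)

    sizes = sorted({int(h.sum()) for h in kept.values()})
    for col in expr.columns:
        ranks = stats.rankdata(expr[col].to_numpy(), method="average")
        z = (ranks - ranks.mean()) / ranks.std(ddof=1)
        null_mean_pos: dict[int, float] = {}
        null_mean_neg: dict[int, float] = {}
        for m in sizes:
            null = np.empty(nperm)
            for b in range(nperm):
                h = np.zeros(N, dtype=bool)
                h[rng.choice(N, size=m, replace=False)] = True
                null[b] = ssgsea_sample_es(z, h, weight)
            pos, neg = null[null > 0], null[null < 0]
            null_mean_pos[m] = float(np.abs(pos).mean()) if len(pos) else np.nan
            null_mean_neg[m] = float(np.abs(neg).mean()) if len(neg) else np.nan
        for name, h in kept.items():
            es = ssgsea_sample_es(z, h, weight)
            denom = null_mean_pos[int(h.sum())] if es > 0 else null_mean_neg[int(h.sum())]
            nes.loc[name, col] = 0.0 if es == 0 or not np.isfinite(denom) else es / denom
    nes.attrs["excluded"] = skipped

    rng_ = nes.max(axis=1) - nes.min(axis=1)
    scaled = nes.sub(nes.min(axis=1), axis=0).div(rng_.where(rng_ > 0, 1.0), axis=0)
    scaled.attrs["excluded"] = skipped
    return nes, scaled
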