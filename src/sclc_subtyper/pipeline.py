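"""End-to-end orchestration: config handling, the packaged cell-line table,
stage execution with derived seeds, and a hashed output manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as annotation_mod  # noqa: F401  (re-export convenience)
from . import differential, enrichment, io, preprocess, scores, splsda, synthetic_data, unsupervised
from .core import SUBTYPES, derive_seed

_CULTURE_MAP = {
    "Adherent": "adherent",
    "Semi-adherent": "semi-adherent",
    "Suspension": "suspension",
}


def load_cell_line_table(path=None) -> pd.DataFrame:
    """Load a cell-line annotation table (defaults to the packaged 26-line
    fixture) and validate subtype / culture-type vocabularies."""
    if path is None:
        path = resources.files("sclc_subtyper").joinpath("data/cell_lines.tsv")
    text = Path(str(path)).read_text() if not hasattr(path, "read_text") else path.read_text()
    if not text.strip():
        raise ValueError("empty cell line table")
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    need = {"cell_line", "subtype", "origin", "chemotherapy", "culture_type"}
    if not need <= set(df.columns):
        raise ValueError(f"cell line table needs columns {sorted(need)}")
    bad = [s for s in df["subtype"] if not (s.startswith("SCLC-") and s[5:] in SUBTYPES)]
    if bad:
        raise ValueError(f"unknown subtype token(s): {bad[:3]}")
    df["subtype"] = df["subtype"].str[5:]
    bad = [c for c in df["culture_type"] if c not in _CULTURE_MAP]
    if bad:
        raise ValueError(f"unknown culture type token(s): {bad[:3]}")
    df["culture_type"] = df["culture_type"].map(_CULTURE_MAP)
    return df


@dataclass
class PipelineConfig:
    """All stage parameters with defaults matching the published analysis."""

    out_dir: str = "run"
    seed: int = 0
    # synthetic data
    n_proteins: int = 800
    n_specific_per_subtype: int = 20
    # 3.0 log2 keeps planted proteins above the 1.25-SD clustering filter
    # (a +/-2 shift in one of four subtypes gives across-sample SD ~ 0.9)
    subtype_effect: float = 3.0
    batch_shift: float = 1.0
    # enough replicate noise to keep the rank metric graded; a near-noiseless
    # matrix makes every planted protein's p collapse and the weighted KS
    # statistic saturate for any set touching one of them
    noise_sd: float = 0.8
    marker_effect: float = 1.5
    missing_midpoint: float = 16.5
    missing_slope: float = 1.0
    geneset_sizes: tuple = (15,)
    n_null_sets: int = 20
    # preprocess
    min_frac: float = 0.8
    width: float = 0.3
    downshift: float = 1.8
    on_off_hi: float = 0.85
    on_off_lo: float = 0.15
    # unsupervised
    sd_thr: float = 1.25
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 0.8
    k_min: int = 2
    k_max: int = 7
    # enrichment
    nperm: int = 1000
    p_thr: float = 0.01
    p_other: float = 0.1
    min_overlap: int = 5
    ssgsea_weight: float = 0.75
    # splsda
    folds: int = 3
    repeats: int = 50
    max_components: int = 3
    keepX_grid: tuple = (5, 10, 20)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("geneset_sizes", "keepX_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geneset_sizes"] = list(d["geneset_sizes"])
        d["keepX_grid"] = list(d["keepX_grid"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> preprocess -> scores -> DE -> enrichment -> clustering
    -> sPLS-DA on synthetic data; write stage TSVs and a hashed manifest.

    Rerunning with the same config and seed reproduces identical hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    # --- simulate
    sim_cfg = synthetic_data.SimulationConfig(
        n_proteins=config.n_proteins,
        n_specific_per_subtype=config.n_specific_per_subtype,
        subtype_effect=config.subtype_effect,
        batch_shift=config.batch_shift,
        noise_sd=config.noise_sd,
        marker_effect=config.marker_effect,
        missing_midpoint=config.missing_midpoint,
        missing_slope=config.missing_slope,
        geneset_sizes=tuple(config.geneset_sizes),
        seed=derive_seed(config.seed, "simulate"),
    )
    raw, ann, truth = synthetic_data.generate_dataset(sim_cfg)
    raw = synthetic_data.inject_missingness(
        raw, config.missing_midpoint, config.missing_slope, derive_seed(config.seed, "missing")
    )
    gsets = synthetic_data.generate_genesets(
        truth, config.geneset_sizes, config.n_null_sets, derive_seed(config.seed, "genesets")
    )
    io.write_intensity_tsv(raw, out / "raw_intensities.tsv")
    io.write_annotation_tsv(ann, out / "annotation.tsv")
    io.write_gmt(gsets, out / "genesets.gmt")
    io.write_json(truth.to_dict(), out / "truth.json")
    note(f"simulate: {raw.values.shape[0]} proteins x {raw.values.shape[1]} measurements")

    # --- preprocess
    norm = preprocess.log2_median_normalize(raw)
    vm, vial_ann = preprocess.vial_median(norm, ann)
    corrected = preprocess.correct_batch(vm, vial_ann)
    aggregated, line_ann = preprocess.replicate_mean(corrected, vial_ann)
    filtered = preprocess.filter_valid(aggregated, config.min_frac)
    note(f"filter: {filtered.values.shape[0]} proteins pass >= {config.min_frac:.0%} valid")
    # on/off candidates come from the unfiltered table: near-absent presence
    # in three subtypes usually fails the 80% rule by construction
    onoff = preprocess.detect_on_off(aggregated, line_ann, config.on_off_hi, config.on_off_lo)
    imputed = preprocess.impute_normal(
        filtered, config.width, config.downshift, derive_seed(config.seed, "impute")
    )
    io.write_intensity_tsv(imputed, out / "processed_log2.tsv")
    io.write_mask_tsv(imputed, out / "processed_mask.tsv")
    io.write_annotation_tsv(line_ann, out / "cell_line_annotation.tsv")
    pd.DataFrame(
        [{"protein": c.protein, "subtype": c.subtype, "direction": c.direction} for c in onoff]
    ).to_csv(out / "on_off_calls.tsv", sep="\t", index=False)
    note(f"on/off calls: {len(onoff)}")

    # --- scores
    markers = {k: [p for p, g in truth.marker_membership.items() if g == k]
               for k in ("NE", "nonNE", "epi", "mes")}
    ne_sig = scores.MarkerSignature("NE", frozenset(markers["NE"]), frozenset(markers["nonNE"]))
    emt_sig = scores.MarkerSignature("EMT", frozenset(markers["mes"]), frozenset(markers["epi"]))
    ne = scores.signature_score(imputed, ne_sig)
    emt = scores.signature_score(imputed, emt_sig)
    r, p = scores.score_association(ne, emt)
    scores.score_table_frame([ne, emt]).to_csv(out / "scores.tsv", sep="\t")
    note(f"NE-EMT association: r={r:.3f}, p={p:.2e}")

    # --- differential expression
    labels = pd.Series(line_ann["subtype"].values, index=line_ann["cell_line"].values)
    de = differential.anova_tukey(imputed.values, labels.loc[list(imputed.samples)])
    de.to_long().to_csv(out / "de_subtype.tsv", sep="\t", index=False)
    specific = {s: differential.subtype_specific(de, s) for s in SUBTYPES}
    pd.concat(
        [df.assign(subtype=s) for s, df in specific.items()]
    ).to_csv(out / "subtype_specific.tsv", sep="\t")
    note("subtype-specific counts: " + ", ".join(f"{s}={len(d)}" for s, d in specific.items()))

    # --- enrichment
    enr_seed = derive_seed(config.seed, "enrichment")
    characteristic = {}
    for s in SUBTYPES:
        comps = {}
        for o in [g for g in SUBTYPES if g != s]:
            ranked = differential.rank_metric(de, (s, o))["score"]
            comps[o] = enrichment.prerank_gsea(
                ranked, gsets, nperm=config.nperm, seed=enr_seed, min_size=config.min_overlap
            )
        characteristic[s] = enrichment.subtype_characteristic(comps, p_thr=config.p_thr)
    pd.concat(
        [df.assign(subtype=s) for s, df in characteristic.items()]
    ).to_csv(out / "characteristic_sets.tsv", sep="\t")
    note("characteristic sets: " + ", ".join(f"{s}={len(d)}" for s, d in characteristic.items()))

    # --- unsupervised
    hv = unsupervised.high_variance_filter(imputed, config.sd_thr)
    cr = unsupervised.consensus_cluster(
        hv,
        k_range=range(config.k_min, config.k_max + 1),
        reps=config.reps,
        p_item=config.p_item,
        p_feature=config.p_feature,
        seed=derive_seed(config.seed, "consensus"),
    )
    k, sil = unsupervised.select_k(cr)
    cr.consensus[k].to_csv(out / "consensus_matrix.tsv", sep="\t")
    pd.DataFrame({"sample": cr.assignments[k].index, "cluster": cr.assignments[k].values}).to_csv(
        out / "cluster_assignment.tsv", sep="\t", index=False
    )
    sil.to_csv(out / "silhouette.tsv", sep="\t", index=False)
    factors = line_ann.set_index("cell_line")[["subtype", "culture_type", "batch"]] if (
        "batch" in line_ann.columns
    ) else line_ann.set_index("cell_line")[["subtype", "culture_type"]]
    pv = unsupervised.pvca(imputed, factors)
    pv.rename("fraction").to_csv(out / "pvca.tsv", sep="\t", index_label="factor")
    note(f"selected K={k}; PVCA: " + ", ".join(f"{i}={v:.2f}" for i, v in pv.items()))

    # --- sPLS-DA
    X = imputed.values.T
    y = labels.loc[list(imputed.samples)].values
    tuning = splsda.tune_splsda(
        X, y, config.max_components, list(config.keepX_grid),
        folds=config.folds, repeats=config.repeats, seed=derive_seed(config.seed, "splsda"),
    )
    model = splsda.fit_splsda(X, y, tuning.n_components, list(tuning.chosen_keepX))
    sel = model.selected_features()
    pattern = splsda.expression_pattern(X, y, sel)
    sel_df = pd.DataFrame({"stability": tuning.stability.reindex(sel)}).join(pattern)
    sel_df.to_csv(out / "splsda_selected.tsv", sep="\t", index_label="protein")
    io.write_json(
        {
            "n_components": tuning.n_components,
            "keepX": list(tuning.chosen_keepX),
            "cv_ber": tuning.ber,
            "centroids": {c: model.centroids.loc[c].tolist() for c in model.classes},
        },
        out / "splsda_model.json",
    )
    note(f"sPLS-DA: {tuning.n_components} comps, keepX={list(tuning.chosen_keepX)}, "
         f"BER={tuning.ber:.3f}")

    # --- manifest
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    manifest = {
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
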