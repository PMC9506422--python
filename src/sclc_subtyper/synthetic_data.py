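"""Synthetic dataset generator with planted ground truth.

Generates protein-by-measurement intensity matrices with the statistical
structure the downstream analysis assumes: log-normal intensities, planted
subtype-specific mean shifts, per-protein additive batch effects,
culture-type effects on a disjoint protein set, replicate noise,
intensity-dependent (left-censored) missingness, marker signatures with
NE-high / NE-low and negatively coupled EMT structure, and gene set
collections enriched for the planted proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CULTURE_TYPES, SUBTYPES, IntensityMatrix


@dataclass(frozen=True)
class SampleSpec:
    cell_line_id: str
    subtype: str
    batch: str
    culture_type: str
    n_bio_replicates: int = 1
    n_tech_replicates: int = 3


def default_samples() -> list[SampleSpec]:
    """26 cell lines (8/7/4/7 per subtype), 2 batches, 3 technical replicates,
    with a 13/3/10 adherent / semi-adherent / suspension split."""
    layout = [
        ("A", 8, ["semi-adherent", "adherent", "suspension", "adherent",
                  "adherent", "suspension", "suspension", "adherent"]),
        ("N", 7, ["suspension", "semi-adherent", "suspension", "adherent",
                  "suspension", "semi-adherent", "suspension"]),
        ("P", 4, ["suspension", "adherent", "suspension", "suspension"]),
        ("Y", 7, ["adherent"] * 7),
    ]
    specs = []
    i = 0
    for subtype, n, cultures in layout:
        for j in range(n):
            specs.append(
                SampleSpec(
                    cell_line_id=f"CL{subtype}{j + 1}",
                    subtype=subtype,
                    batch="B1" if i % 2 == 0 else "B2",
                    culture_type=cultures[j],
                )
            )
            i += 1
    return specs


@dataclass
class SimulationConfig:
    n_proteins: int = 2000
    samples: list[SampleSpec] = field(default_factory=default_samples)
    baseline_mean: float = 20.0
    protein_sd: float = 1.5
    subtype_effect: float = 2.0
    n_specific_per_subtype: int = 50
    batch_shift: float = 1.0
    culture_effect: float = 1.0
    n_culture_proteins: int = 50
    noise_sd: float = 0.3
    missing_midpoint: float = 16.5
    missing_slope: float = 1.0
    geneset_sizes: tuple[int, ...] = (15,)
    marker_counts: tuple[int, int, int, int] = (10, 10, 10, 10)
    marker_effect: float | None = None
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_specific_per_subtype": self.n_specific_per_subtype,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.samples:
            raise ValueError("empty sample list")
        ids = [s.cell_line_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell_line_id in sample list")
        for s in self.samples:
            if s.subtype not in SUBTYPES:
                raise ValueError(f"unknown subtype {s.subtype!r} for {s.cell_line_id}")
            if s.culture_type not in CULTURE_TYPES:
                raise ValueError(f"unknown culture type {s.culture_type!r}")
            if s.n_bio_replicates <= 0 or s.n_tech_replicates <= 0:
                raise ValueError("replicate counts must be > 0")
        if any(c <= 0 for c in self.marker_counts):
            raise ValueError("marker counts must be > 0")
        n_needed = (
            4 * self.n_specific_per_subtype
            + self.n_culture_proteins
            + sum(self.marker_counts)
        )
        if n_needed > self.n_proteins:
            raise ValueError(
                f"n_proteins={self.n_proteins} too small for "
                f"{n_needed} planted/marker/culture proteins"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth — the oracle for recovery tests."""

    specific_proteins: dict[str, dict[str, int]]  # subtype -> {protein: +1/-1}
    batch_assignment: dict[str, str]  # measurement_id -> batch
    enriched_sets: dict[tuple[str, str], list[str]]  # (subtype, dir) -> set names
    marker_membership: dict[str, str]  # protein -> NE/nonNE/epi/mes/culture/none
    batch_deltas: dict[str, float]  # protein -> additive shift in second batch
    universe: list[str]

    def planted_proteins(self) -> set[str]:
        return {p for d in self.specific_proteins.values() for p in d}

    def to_dict(self) -> dict:
        return {
            "specific_proteins": self.specific_proteins,
            "batch_assignment": self.batch_assignment,
            "enriched_sets": {
                f"{s}:{d}": names for (s, d), names in self.enriched_sets.items()
            },
            "marker_membership": self.marker_membership,
            "batch_deltas": self.batch_deltas,
            "universe": self.universe,
        }


# marker group -> subtypes in which the marker is shifted up; NE markers are
# high in the neuroendocrine subtypes (A, N), non-NE in P/Y, mesenchymal in Y
# and epithelial in A/P so the NE and EMT scores are negatively coupled
_MARKER_UP = {
    "NE": ("A", "N"),
    "nonNE": ("P", "Y"),
    "epi": ("A", "P"),
    "mes": ("Y",),
}

_CULTURE_WEIGHT = {"adherent": 0.0, "semi-adherent": 0.5, "suspension": 1.0}


def generate_dataset(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a raw (linear-scale) intensity matrix plus annotation and truth.

    Log2 intensity model per measurement:
    baseline + protein effect + subtype effect (planted proteins only)
    + per-protein batch shift + culture-type effect + replicate noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    protein_effect = rng.normal(0.0, config.protein_sd, size=config.n_proteins)

    # partition planted protein roles over a shuffled id order
    order = rng.permutation(config.n_proteins)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        ids = [proteins[i] for i in order[cursor : cursor + n]]
        cursor += n
        return ids

    specific: dict[str, dict[str, int]] = {}
    for subtype in SUBTYPES:
        ids = take(config.n_specific_per_subtype)
        signs = rng.choice([-1, 1], size=len(ids))
        specific[subtype] = {p: int(s) for p, s in zip(ids, signs)}

    culture_proteins = take(config.n_culture_proteins)

    marker_membership: dict[str, str] = {}
    for group, n in zip(("NE", "nonNE", "epi", "mes"), config.marker_counts):
        for p in take(n):
            marker_membership[p] = group

    marker_effect = (
        config.subtype_effect if config.marker_effect is None else config.marker_effect
    )

    # per-protein batch delta with random sign: survives median normalization
    # (median shift across proteins ~ 0) while still a pure per-protein shift
    batch_sign = rng.choice([-1.0, 1.0], size=config.n_proteins)
    batch_delta = batch_sign * config.batch_shift

    # per-protein log2 offset by subtype, assembled once
    subtype_offset = {s: np.zeros(config.n_proteins) for s in SUBTYPES}
    pindex = {p: i for i, p in enumerate(proteins)}
    for subtype, members in specific.items():
        for p, sign in members.items():
            subtype_offset[subtype][pindex[p]] += sign * config.subtype_effect
    for p, group in marker_membership.items():
        for subtype in _MARKER_UP[group]:
            subtype_offset[subtype][pindex[p]] += marker_effect

    culture_idx = np.array([pindex[p] for p in culture_proteins], dtype=int)

    columns: list[str] = []
    rows_ann: list[dict] = []
    data = np.empty((config.n_proteins, 0))
    cols_data: list[np.ndarray] = []
    batch_assignment: dict[str, str] = {}
    for spec in config.samples:
        for bio in range(1, spec.n_bio_replicates + 1):
            for tech in range(1, spec.n_tech_replicates + 1):
                mid = f"{spec.cell_line_id}_b{bio}_t{tech}"
                if mid in batch_assignment:
                    raise ValueError(f"duplicate measurement id {mid}")
                col = (
                    config.baseline_mean
                    + protein_effect
                    + subtype_offset[spec.subtype]
                    + rng.normal(0.0, config.noise_sd, size=config.n_proteins)
                )
                if spec.batch != config.samples[0].batch:
                    col = col + batch_delta
                cw = _CULTURE_WEIGHT[spec.culture_type]
                if cw and config.culture_effect:
                    col = col.copy()
                    col[culture_idx] += cw * config.culture_effect
                cols_data.append(col)
                columns.append(mid)
                batch_assignment[mid] = spec.batch
                rows_ann.append(
                    {
                        "measurement_id": mid,
                        "cell_line": spec.cell_line_id,
                        "subtype": spec.subtype,
                        "batch": spec.batch,
                        "culture_type": spec.culture_type,
                        "bio_rep": str(bio),
                        "tech_rep": str(tech),
                    }
                )
    data = np.column_stack(cols_data)

    values = pd.DataFrame(
        np.exp2(data), index=pd.Index(proteins, name="protein_id"), columns=columns
    )
    matrix = IntensityMatrix(values=values, scale="linear", stage="raw")
    ann = pd.DataFrame(rows_ann)
    truth = SyntheticTruth(
        specific_proteins=specific,
        batch_assignment=batch_assignment,
        enriched_sets={},
        marker_membership={
            p: marker_membership.get(p, "culture" if p in set(culture_proteins) else "none")
            for p in proteins
            if p in marker_membership or p in set(culture_proteins)
        },
        batch_deltas={p: float(batch_delta[i]) for i, p in enumerate(proteins)},
        universe=list(proteins),
    )
    return matrix, ann, truth


def inject_missingness(
    matrix: IntensityMatrix, midpoint: float, slope: float, seed: int
) -> IntensityMatrix:
    """Blank entries under a logistic detection model.

    Missing probability = 1 / (1 + exp(slope * (x - midpoint))) where x is the
    log2 intensity, so lower-intensity entries are more likely to be missing
    (left censoring). slope=0 gives uniform probability 0.5.
    """
    if slope < 0:
        raise ValueError(f"slope must be >= 0, got {slope}")
    rng = np.random.default_rng(seed)
    x = matrix.values.to_numpy(dtype=float)
    log2x = np.log2(x) if matrix.scale == "linear" else x
    with np.errstate(over="ignore"):
        p_missing = 1.0 / (1.0 + np.exp(slope * (log2x - midpoint)))
    drop = rng.random(size=x.shape) < p_missing
    out = matrix.values.where(~drop)
    return matrix.with_values(out)


def expected_missing_fraction(matrix: IntensityMatrix, midpoint: float, slope: float) -> float:
    """Model-implied mean missing probability over the matrix entries."""
    x = matrix.values.to_numpy(dtype=float)
    log2x = np.log2(x) if matrix.scale == "linear" else x
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(slope * (log2x - midpoint)))
    return float(np.mean(p))


def generate_genesets(
    truth: SyntheticTruth,
    sizes,
    n_null_sets: int,
    seed: int,
    planted_fraction: float = 1.0,
    subtypes=SUBTYPES,
) -> dict[str, list[str]]:
    """Build a gene set collection with planted enriched sets plus null sets.

    For each subtype one enriched set per requested size is created from its
    up-planted proteins (topped up with random universe members when
    ``planted_fraction`` < 1 or planted proteins run out). Null sets are
    uniform draws from the universe. Enriched set names are recorded in
    ``truth.enriched_sets``.
    """
    sizes = list(sizes)
    if any(s < 5 for s in sizes):
        raise ValueError("gene set sizes must be >= 5")
    universe = list(truth.universe)
    if any(s > len(universe) for s in sizes):
        raise ValueError("requested set size exceeds universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for subtype in subtypes:
        up = sorted(p for p, sign in truth.specific_proteins.get(subtype, {}).items() if sign > 0)
        for k, size in enumerate(sizes):
            n_planted = min(int(round(planted_fraction * size)), len(up))
            members = list(rng.choice(up, size=n_planted, replace=False)) if n_planted else []
            pool = [p for p in universe if p not in set(members)]
            fill = size - len(members)
            if fill:
                members += list(rng.choice(pool, size=fill, replace=False))
            name = f"PLANTED_{subtype}_UP_{k + 1}"
            sets[name] = members
            truth.enriched_sets.setdefault((subtype, "up"), []).append(name)
    for k in range(n_null_sets):
        size = sizes[k % len(sizes)]
        sets[f"NULL_{k + 1}"] = list(rng.choice(universe, size=size, replace=False))
    return sets
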