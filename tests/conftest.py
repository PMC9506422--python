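import numpy as np
import pandas as pd
import pytest

from sclc_subtyper import synthetic_data as sd
from sclc_subtyper.core import IntensityMatrix


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        n_proteins=400,
        n_specific_per_subtype=10,
        subtype_effect=2.0,
        batch_shift=1.0,
        noise_sd=0.3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(raw matrix, measurement annotation, truth) at modest size."""
    return sd.generate_dataset(small_config)


@pytest.fixture()
def toy_matrix():
    """4 proteins x 4 samples, log2 scale, no missing values."""
    values = pd.DataFrame(
        [
            [20.0, 21.0, 19.0, 20.0],
            [18.0, 18.5, 17.5, 18.0],
            [22.0, 22.0, 22.0, 22.0],
            [15.0, 16.0, 17.0, 18.0],
        ],
        index=["P1", "P2", "P3", "P4"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return IntensityMatrix(values=values, scale="log2", stage="imputed")


def cell_line_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    return ann.drop_duplicates("cell_line").reset_index(drop=True)


def subtype_labels(ann: pd.DataFrame) -> pd.Series:
    lines = cell_line_annotation(ann)
    return pd.Series(lines["subtype"].values, index=lines["cell_line"].values)


@pytest.fixture(scope="session")
def flat_samples():
    """Sample layout with one measurement per cell line (no replicates)."""
    return [
        sd.SampleSpec(s.cell_line_id, s.subtype, s.batch, s.culture_type, 1, 1)
        for s in sd.default_samples()
    ]
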