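import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ucrtile as u

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-region simulated dataset shared by read-only tests."""
    cfg = u.SimConfig(n_regions=30, n_de_up=3, n_de_down=3,
                      de_log2fold_range=(1.0, 2.0), seed=7)
    return u.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    smoothed, tucrs = u.preprocess_matrix(small_dataset.intensities,
                                   small_dataset.probes)
    return smoothed, tucrs


@pytest.fixture
def toy_regions():
    """Three hand-made regions: intergenic, intronic on +, exonic on -."""
    return [
        u.UCRegion("r.inter", "chr1", 10000, 10300, "intergenic"),
        u.UCRegion("r.plus", "chr1", 50000, 50250, "intronic", "GENEA", "+"),
        u.UCRegion("r.minus", "chr1", 90000, 90400, "exonic", "GENEB", "-"),
    ]


def make_tucr_matrix(values: dict, lines=("SK-N-BE", "LAN-5", "SH-SY5Y")):
    """TUCRMatrix from {transcript: [12 log2 values]} with the standard sheet."""
    samples = u.simulate.make_sample_sheet()
    df = pd.DataFrame(values, index=samples.index).T
    return u.TUCRMatrix(values=df, samples=samples)


@pytest.fixture
def tucr_factory():
    return make_tucr_matrix
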