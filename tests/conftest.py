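import numpy as np
import pytest

from mirdem import synthetic_data as synth
from mirdem.io_formats import ExpressionDataset


@pytest.fixture(scope="session")
def codown_features():
    return synth.codown_cluster_fixture()


@pytest.fixture
def tiny_dataset():
    """3 probes x 6 samples (two groups of 3) with hand-set flags."""
    intensities = np.array(
        [
            [100.0, 110.0, 90.0, 400.0, 420.0, 380.0],
            [200.0, 210.0, 190.0, 100.0, 95.0, 105.0],
            [50.0, 55.0, 45.0, 50.0, 52.0, 48.0],
        ]
    )
    present = np.array(
        [
            [True, True, True, True, True, True],
            [True, True, False, True, True, True],
            [False, False, False, False, False, False],
        ]
    )
    samples = ["A_r1", "A_r2", "A_r3", "B_r1", "B_r2", "B_r3"]
    groups = {s: s.split("_")[0] for s in samples}
    return ExpressionDataset(
        probe_ids=["p1", "p2", "p3"],
        sample_ids=samples,
        intensities=intensities,
        present=present,
        groups=groups,
    )
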