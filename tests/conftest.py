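import numpy as np
import pytest

from dbnsurv.io import ClinicalTable, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    return OmicsMatrix(
        modality="gene",
        sample_ids=["S1", "S2", "S3"],
        probe_ids=["P1", "P2"],
        values=np.array([[1.0, 4.0], [2.0, 5.5], [3.0, -1.25]]),
    )


@pytest.fixture
def tiny_clinical():
    return ClinicalTable(
        sample_ids=["S1", "S2", "S3", "S4"],
        survival_time=np.array([2190.0, 1100.0, 730.0, 3000.0]),
        vital_status=["alive", "deceased", "alive", "deceased"],
    )
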