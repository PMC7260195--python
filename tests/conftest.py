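import numpy as np
import pytest

from cytogate.io import EventMatrix, write_fcs


@pytest.fixture
def tiny_matrix():
    """2-channel, 3-event matrix with known values."""
    return EventMatrix(
        sample_id="tiny",
        channels=["FSC-A", "CD3"],
        data=np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]]),
        metadata={"DATE": "01-JAN-2024", "CYT": "SimCyt"},
    )


@pytest.fixture
def fcs_file(tmp_path, tiny_matrix):
    path = tmp_path / "tiny.fcs"
    write_fcs(tiny_matrix, path)
    return path


@pytest.fixture
def bimodal():
    """Equal mixture of N(0, 0.2^2) and N(4, 0.2^2); true valley at 2."""
    rng = np.random.default_rng(42)
    return np.concatenate([rng.normal(0, 0.2, 5000), rng.normal(4, 0.2, 5000)])
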