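import numpy as np
import pytest

from stemstate import synth


@pytest.fixture(scope="session")
def state_configs():
    return synth.default_state_configs()


@pytest.fixture(scope="session")
def mixtures():
    return synth.default_mixtures()


@pytest.fixture(scope="session")
def sparse_field():
    """One 1024x1024 FLIM field with 50 non-touching cells (Day 14 mixture)."""
    field, gt = synth.generate_field(
        1024, 1024, 50, synth.default_mixtures()[2], seed=3, allow_touching=False
    )
    return field, gt


@pytest.fixture(scope="session")
def sparse_window_matrix(sparse_field):
    from stemstate.segment import estimate_window_matrix

    _, gt = sparse_field
    sizes = [
        (float(np.ptp(r.cell_polygon[:, 0])), float(np.ptp(r.cell_polygon[:, 1])))
        for r in gt.records
    ]
    return estimate_window_matrix(sizes)


@pytest.fixture(scope="session")
def sparse_detections(sparse_field, sparse_window_matrix):
    from stemstate.segment import detect_cells

    field, _ = sparse_field
    return detect_cells(field, sparse_window_matrix)
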