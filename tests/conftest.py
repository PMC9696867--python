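import numpy as np
import pytest

from premcat.databank import GpcmItem, ItemBank, ResponseMatrix
from premcat.simulate import paper_like_design, simulate_responses


@pytest.fixture(scope="session")
def small_bank():
    """Three items with distinct discriminations and threshold locations."""
    return ItemBank([
        GpcmItem("A", 2.5, (-0.5, 0.5)),
        GpcmItem("B", 1.0, (-0.5, 0.5)),
        GpcmItem("C", 1.6, (-1.5, 0.0, 0.8, 1.4)),
    ])


@pytest.fixture(scope="session")
def study_design():
    """Study-like design: 499 respondents, 19 five-category items."""
    return paper_like_design(seed=20260922)


@pytest.fixture(scope="session")
def study_data(study_design):
    data, theta = simulate_responses(study_design)
    return data, theta


@pytest.fixture(scope="session")
def study_thetas(study_design, study_data):
    from premcat.calibration import eap_score_matrix
    data, _ = study_data
    return eap_score_matrix(data, study_design.bank)


def make_matrix(values, item_ids=None, **kw):
    values = np.asarray(values, dtype=float)
    ids = item_ids or [f"I{j + 1}" for j in range(values.shape[1])]
    return ResponseMatrix(values=values, item_ids=ids, **kw)
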