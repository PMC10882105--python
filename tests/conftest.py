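import numpy as np
import pytest

from cdaction import HillParams, SurvivalTable


@pytest.fixture
def hill_a():
    return HillParams(k=5.0, n=1.5, drug_label="A")


@pytest.fixture
def hill_b():
    return HillParams(k=8.0, n=2.0, drug_label="B")


@pytest.fixture
def exp_curve():
    """Exponential-ish survival step curve on a regular monthly grid."""
    t = np.arange(0.0, 24.0 + 1e-9, 0.5)
    return SurvivalTable(t, np.exp(-t / 8.0), n_patients=200, label="exp")


def write_csv(path, text):
    path.write_text(text)
    return str(path)
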