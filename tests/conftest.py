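import numpy as np
import pandas as pd
import pytest

from circatf import OmicsMatrix, RunConfig, StudyConfig, simulate_study

TWO_CYCLE = list(range(0, 48, 3))


@pytest.fixture
def config():
    return RunConfig(seed=7)


@pytest.fixture
def matrix_factory():
    """Build an OmicsMatrix from a feature->row dict."""

    def build(rows: dict, layer="tf_dba", timepoints=TWO_CYCLE, norm_state="raw"):
        df = pd.DataFrame.from_dict(rows, orient="index", columns=timepoints, dtype=float)
        df.index.name = "feature"
        return OmicsMatrix(layer=layer, data=df, norm_state=norm_state)

    return build


@pytest.fixture(scope="session")
def default_bundle():
    """Mid-sized synthetic study shared across read-only tests."""
    return simulate_study(StudyConfig(seed=11))


def cosine(timepoints, baseline, amplitude, acrophase, period=24.0):
    t = np.asarray(timepoints, dtype=float)
    return baseline + amplitude * np.cos(2 * np.pi * (t - acrophase) / period)
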