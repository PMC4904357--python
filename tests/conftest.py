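import numpy as np
import pandas as pd
import pytest

from parturitrack import counts as counts_mod
from parturitrack import simdata


@pytest.fixture
def tiny_cm():
    """6 genes x 4 samples, two groups, hand-sized counts."""
    rng = np.random.default_rng(42)
    vals = rng.integers(5, 200, size=(6, 4))
    counts = pd.DataFrame(vals, index=[f"g{i}" for i in range(6)],
                          columns=["s1", "s2", "s3", "s4"])
    sheet = pd.DataFrame({
        "species": "mouse", "model": "term",
        "group": ["A", "A", "B", "B"], "treatment": "none",
        "pseudotime": [0.0, 0.0, 1.0, 1.0],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    return counts_mod.CountMatrix(counts, sheet)


@pytest.fixture(scope="session")
def small_sim():
    """One default-condition simulated mouse dataset, shared across tests."""
    cfg = simdata.SimConfig(seed=7)
    cm, truth = simdata.simulate_mouse_models(cfg)
    return cfg, cm, truth
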