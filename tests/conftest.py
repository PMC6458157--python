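import numpy as np
import pandas as pd
import pytest

from mirnascreen.data import CountMatrix, ProbeClass
from mirnascreen.simulate import SimConfig, simulate_cohort


@pytest.fixture
def toy_counts() -> CountMatrix:
    """2 samples × (2 endogenous + 3 negative-control) probes."""
    counts = pd.DataFrame(
        {
            "mirA": [10.0, 20.0],
            "mirB": [5.0, 8.0],
            "NEG_A": [1.0, 2.0],
            "NEG_B": [2.0, 2.0],
            "NEG_C": [3.0, 2.0],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    annotation = {
        "mirA": ProbeClass.ENDOGENOUS,
        "mirB": ProbeClass.ENDOGENOUS,
        "NEG_A": ProbeClass.NEG_CONTROL,
        "NEG_B": ProbeClass.NEG_CONTROL,
        "NEG_C": ProbeClass.NEG_CONTROL,
    }
    return CountMatrix(counts=counts, annotation=annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated serial cohort shared by read-only tests."""
    cfg = SimConfig(
        seed=42,
        n_per_group={"TERM": 10, "PRETERM": 8, "SHORT": 8},
        n_probes=120,
        n_expressed=30,
        patient_sd=0.5,
        haemolysis_fraction=0.0,
    )
    return cfg, *simulate_cohort(cfg)
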