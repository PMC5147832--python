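import numpy as np
import pandas as pd
import pytest

from smokewas import simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small full study: 10 never / 20 current smokers, 300 probes."""
    return simulate_cohort(n_never=10, n_current=20, n_probes=300,
                           n_discriminating=10, seed=7)


@pytest.fixture(scope="session")
def cell_study():
    """Sorted-cell study sized like a small validation cohort (14/20)."""
    return simulate_cohort(
        n_never=14, n_current=20, n_probes=200, n_discriminating=10,
        noise_sd=0.1,
        class_counts={"myeloid_plus_B": 3, "lymphoid": 3, "T_only": 2,
                      "monocyte_only": 2, "pan_cell": 2},
        seed=11)


@pytest.fixture()
def toy_matrix():
    probes = [f"cg{i:08d}" for i in range(1, 6)]
    samples = ["s1", "s2", "s3", "s4"]
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.uniform(0.1, 0.9, size=(5, 4)),
                        index=pd.Index(probes, name="probe_id"),
                        columns=samples)


@pytest.fixture()
def toy_sheet():
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(1, 9)],
        "smoking_status": ["never"] * 4 + ["current"] * 4,
        "cigarettes_per_day": [0.0] * 4 + [15.0, 20.0, 30.0, 40.0],
        "years_smoked": [0.0] * 4 + [5.0, 10.0, 20.0, 25.0],
        "pack_years": [0.0] * 4 + [3.75, 10.0, 30.0, 50.0],
        "cotinine": [1.0, 2.0, 0.5, 3.0, 120.0, 150.0, 300.0, 350.0],
        "age": [30.0, 40.0, 25.0, 55.0, 35.0, 50.0, 44.0, 28.0],
        "sex": ["male", "female"] * 4,
        "race": ["white", "black", "white", "white",
                 "black", "white", "black", "white"],
    })
    return sheet.set_index("sample_id", drop=False)
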