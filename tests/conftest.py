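import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import retestkit as rk

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dataset():
    """The packaged synthetic nine-week study dataset (fixed seed)."""
    dataset, truths = rk.reference_fixture()
    return dataset, truths


@pytest.fixture(scope="session")
def fixture_report(fixture_dataset):
    dataset, _ = fixture_dataset
    return rk.run(rk.RunConfig(), dataset=dataset)


@pytest.fixture()
def small_trials_csv(tmp_path):
    path = tmp_path / "trials.csv"
    rows = ["subject_id,session_id,test,variable,trial_index,value"]
    for trial, value in enumerate([40.0, 42.5, 41.0], start=1):
        rows.append(f"s1,S1,cmj,jump_height,{trial},{value}")
    path.write_text("\n".join(rows) + "\n")
    return path


def random_matrix(rng, n=None, k=None):
    n = n or rng.integers(3, 11)
    k = k or rng.integers(2, 5)
    subject = rng.normal(0, rng.uniform(0.5, 3.0), size=(n, 1))
    noise = rng.normal(0, rng.uniform(0.2, 1.5), size=(n, k))
    shift = rng.normal(0, 0.3, size=(1, k))
    return 10.0 + subject + shift + noise
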