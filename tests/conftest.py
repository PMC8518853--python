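import numpy as np
import pandas as pd
import pytest

from nichepart import DetectionTable, generate, worked_example
from nichepart.synthetic_data import small_config


@pytest.fixture(scope="session")
def worked():
    """Hand-checkable 6-sample / 12-prey fixture plus its manifest."""
    table, assignments, traits, habitat, manifest = worked_example()
    return {
        "table": table,
        "assignments": assignments,
        "traits": traits,
        "habitat": habitat,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def small_sim():
    """One desk-scale synthetic dataset with planted preference effects."""
    return generate(small_config(seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic dataset (9 colonies, 11 dates, 400 prey)."""
    return generate(seed=7)


def random_detection_table(rng, n_samples=5, n_motus=8, max_reads=2000):
    counts = pd.DataFrame(
        rng.integers(0, max_reads, size=(n_samples, n_motus)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"m{j}" for j in range(n_motus)],
    )
    meta = pd.DataFrame(
        {
            "colony_id": ["c1"] * n_samples,
            "species": ["auritus"] * n_samples,
            "sample_type": ["community"] * n_samples,
            "season": ["summer"] * n_samples,
        },
        index=counts.index,
    )
    return DetectionTable(counts, meta)
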