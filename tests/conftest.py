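import numpy as np
import pandas as pd
import pytest

from phyllodiff import CountTable, SimConfig, generate_count_table


@pytest.fixture(scope="session")
def small_config():
    """A reduced study configuration for fast end-to-end tests."""
    return SimConfig(n_annotations=300, n_contaminants=20, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return generate_count_table(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """One table at the full reference conditions."""
    return generate_count_table(SimConfig(seed=7))


def make_table(counts: np.ndarray, treatments=None, classes=None, site="CA"):
    """Hand-construct a CountTable from a raw array."""
    counts = np.asarray(counts, dtype=float)
    n_ann, n_s = counts.shape
    sample_ids = [f"S{j}" for j in range(n_s)]
    if treatments is None:
        half = n_s // 2
        treatments = ["watered"] * half + ["drought"] * (n_s - half)
    if classes is None:
        classes = ["experimental"] * n_s
    frame = pd.DataFrame(counts, index=[f"a{i}" for i in range(n_ann)], columns=sample_ids)
    meta = pd.DataFrame(
        {"site": site, "treatment": treatments, "class": classes},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountTable(frame, meta)
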