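import numpy as np
import pandas as pd
import pytest

import seedtrans as st


@pytest.fixture(scope="session")
def small_counts() -> st.CountTable:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.integers(0, 50, size=(20, 10)),
        index=[f"o{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(10)],
    )
    df.iloc[0] += 1  # guarantee nonzero columns
    return st.CountTable(df)


@pytest.fixture(scope="session")
def full_study():
    """Reduced-compartment synthetic study shared across tests."""
    design = st.StudyDesign(compartments=("BS", "RS", "R", "S1", "L1", "Se"))
    return st.generate_full_study(design=design, seed=7)


@pytest.fixture(scope="session")
def seed_subset(full_study):
    """Progeny-seed subtable + metadata of the full study."""
    table, meta, tax, truth = full_study
    sids = meta.samples(compartment="Se", year=2018)
    sub = table.subset_samples(sids)
    meta_sub = st.SampleMeta(meta.table[meta.table["sample_id"].isin(sids)].copy())
    return sub, meta_sub, truth
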