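import pandas as pd
import pytest

import spcquant as sq


@pytest.fixture(scope="session")
def panel() -> pd.DataFrame:
    return sq.load_reference_panel()


@pytest.fixture(scope="session")
def panel_pooled() -> sq.PooledGroupCounts:
    return sq.panel_pooled_counts()


@pytest.fixture
def tiny_table() -> sq.SpectralCountTable:
    counts = pd.DataFrame(
        {"run1": [1, 0, 5], "run2": [2, 0, 5]},
        index=pd.Index(["P1", "P2", "P3"], name="accession"),
    )
    meta = pd.DataFrame(
        {"gene": ["G1", "G2", "G3"],
         "description": ["one", "two", "three"],
         "length_aa": [100, 200, 300]},
        index=counts.index,
    )
    return sq.SpectralCountTable(counts=counts, meta=meta)


@pytest.fixture
def tiny_design() -> sq.GroupDesign:
    frame = pd.DataFrame(
        {"patient": ["A", "A"], "group": ["grp", "grp"]},
        index=pd.Index(["run1", "run2"], name="run"),
    )
    return sq.GroupDesign(assignments=frame)
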