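import numpy as np
import pandas as pd
import pytest

from pollenet.io_model import CountTable


@pytest.fixture
def toy_counts() -> CountTable:
    """3 taxa x 4 samples with genus-resolved taxonomy."""
    counts = pd.DataFrame(
        [[2, 0, 4, 1], [2, 0, 3, 5], [4, 0, 3, 2]],
        index=["otu1", "otu2", "otu3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    taxonomy = pd.Series(
        {
            "otu1": "k__Bacteria;p__Proteobacteria;c__A;o__B;f__C;g__Gilliamella",
            "otu2": "k__Bacteria;p__Proteobacteria;c__A;o__B;f__C;g__Gilliamella",
            "otu3": "k__Bacteria;p__Firmicutes;c__D;o__E;f__F;g__Lactobacillus",
        }
    )
    return CountTable(counts=counts, taxonomy=taxonomy, domain="bacteria")


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "species": ["CA", "CA", "LA", "LA"],
            "treatment": ["open", "bagging", "open", "bagging"],
            "pollination": ["self", "self", "cross", "cross"],
            "replicate": [1, 1, 1, 1],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
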