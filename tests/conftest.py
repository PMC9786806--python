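import numpy as np
import pandas as pd
import pytest

from seedscreen import reference_data
from seedscreen.summaries import classify_seed_frame


@pytest.fixture(scope="session")
def tree_table():
    return reference_data.tree_table()


@pytest.fixture(scope="session")
def category_table():
    return reference_data.category_table()


@pytest.fixture(scope="session")
def classified_reference(category_table):
    """Reference survey categories run through the pathway engine, one row
    per category with a ``count`` weight."""
    cats = category_table.copy()
    cats["seed_id"] = [f"cat{i}" for i in range(len(cats))]
    cats["mother_id"] = "pooled_" + cats["maternal_level"].astype(int).astype(str) + "x"
    cats["status"] = "ok"
    return classify_seed_frame(cats)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230301)


def expand_to_seeds(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-category weighted frame -> one row per seed (for invariance tests)."""
    rows = classified.loc[classified.index.repeat(classified["count"])].drop(columns="count")
    rows = rows.reset_index(drop=True)
    rows["seed_id"] = [f"s{i}" for i in range(len(rows))]
    return rows
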