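import numpy as np
import pandas as pd
import pytest

from usualintake import IntakeDataset


def dataset_from_pairs(pairs) -> IntakeDataset:
    """Build a two-day dataset from a list of (day1, day2) amount pairs."""
    rows = []
    for i, (a, b) in enumerate(pairs):
        rows.append({"person": i, "day": 1, "amount": float(a)})
        rows.append({"person": i, "day": 2, "amount": float(b)})
    return IntakeDataset(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
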