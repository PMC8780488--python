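import numpy as np
import pandas as pd
import pytest


def make_units(counts_by_field: dict, method: str = "sweep",
               stage: str = "squaring") -> pd.DataFrame:
    """Small sampling-unit frame: one unit per listed count, quadrants cycling."""
    rows = []
    for fid, counts in counts_by_field.items():
        for i, c in enumerate(counts):
            rows.append(dict(
                year=2019, state="NC", district="NC-D1", field_id=fid,
                quadrant=(i % 4) + 1, unit=i // 4 + 1, method=method,
                growth_stage=stage,
                unit_size=100.0 if method == "sweep" else 1.5,
                adults=c, nymphs=0, total=c))
    return pd.DataFrame(rows)


@pytest.fixture
def toy_units():
    return make_units({"A": [10, 10, 2, 10], "B": [1, 1, 1, 1]})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
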