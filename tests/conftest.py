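import numpy as np
import pandas as pd
import pytest

import seedlingfit as sf


@pytest.fixture(scope="session")
def lines():
    return sf.default_lines()


@pytest.fixture(scope="session")
def schemes(lines):
    return sf.all_schemes(lines)


@pytest.fixture(scope="session")
def maphe(schemes):
    return schemes["MAPHE"]


@pytest.fixture(scope="session")
def trl_dataset(maphe):
    """Small synthetic total-root-length dataset at study-like scale."""
    cfg = sf.default_config("TRL", plants_per_line=10, seed=1234)
    return sf.simulate_trajectories(cfg)


def make_dataset(rows):
    """Rows of (plant_id, line_id, day, trait, value)."""
    return sf.Dataset(pd.DataFrame(
        rows, columns=["plant_id", "line_id", "day", "trait", "value"]))


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 plants x 4 days, deterministic values, <=30 observations."""
    rng = np.random.default_rng(7)
    rows = []
    for i, line in enumerate(["G19833", "G23419", "G19833xG23419"]):
        for day in (2.0, 4.0, 6.0, 8.0):
            rows.append((f"p{i}", line, day, "TRL",
                         float(rng.uniform(1.0, 50.0))))
    return make_dataset(rows)
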