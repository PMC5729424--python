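import numpy as np
import pandas as pd
import pytest

import envscreen as es


@pytest.fixture(scope="session")
def schema():
    return es.default_schema()


@pytest.fixture(scope="session")
def small_landscape():
    """10x10 tract grid, 25 zips, with disease records; shared read-only."""
    cfg = es.SyntheticConfig(n_rows=10, n_cols=10, tracts_per_zip=4,
                             pop_range=(200, 800), seed=11)
    land = es.generate_indicators(cfg)
    records, zip_table = es.generate_disease(land, cfg)
    return cfg, land, records, zip_table


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_table(schema):
    """Complete 6-unit indicator table over all 20 variables."""
    r = np.random.default_rng(7)
    cols = {"population": r.integers(500, 2000, 6)}
    for v in schema:
        cols[v.name] = r.uniform(0.1, 0.9, 6) if v.transform == "arcsine_sqrt" \
            else r.uniform(1.0, 50.0, 6)
    df = pd.DataFrame(cols, index=pd.Index([f"t{i}" for i in range(6)], name="tract_id"))
    return df
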