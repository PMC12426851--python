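import numpy as np
import pytest

from foresiin import pipeline, simulate
from foresiin.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    """A small planted cohort shared across read-only tests."""
    cfg = simulate.SimConfig(n_patients=400, seed=11)
    return simulate.generate_cohort(cfg, schema)


@pytest.fixture(scope="session")
def small_prepared(schema):
    """Prepared (summarized + split) small cohort for protocol tests."""
    cfg = simulate.SimConfig(n_patients=500, seed=11)
    return pipeline.prepare_cohort(cfg, schema)


def random_visit_table(rng, schema, n_patients=4, n_rows=30):
    """A random long-format visit table over a few patients (helper)."""
    import pandas as pd

    names = schema.names
    rows = []
    for _ in range(n_rows):
        j = rng.integers(0, len(names))
        desc = schema[int(j)]
        if desc.kind == "numeric":
            val = float(rng.normal(desc.mean, desc.sd))
        elif desc.kind == "binary":
            val = float(rng.integers(0, 2))
        else:
            val = float(rng.integers(0, len(desc.category_probs)))
        rows.append(
            {
                "patient_id": int(rng.integers(0, n_patients)),
                "day": int(rng.integers(-730, 1)),
                "feature": names[int(j)],
                "value": val,
            }
        )
    return pd.DataFrame(rows)
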