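import numpy as np
import pytest

from brainage_mi import RegionSchema, default_aging_preset, simulate_cohort


@pytest.fixture(scope="session")
def schema():
    return RegionSchema()


@pytest.fixture(scope="session")
def small_schema(schema):
    """Three anchor regions, both hemispheres, all four measures."""
    return schema.subset(
        regions=["pre_central_gyrus", "cingulate", "insula"],
    )


@pytest.fixture(scope="session")
def demo_cohort(schema):
    """A mid-sized cohort from the default aging preset, with its truth."""
    preset = default_aging_preset(schema, seed=11)
    table, truth = simulate_cohort(preset, schema, n=200, seed=7)
    return table, truth


@pytest.fixture(scope="session")
def small_cohort(small_schema):
    preset = default_aging_preset(small_schema, seed=3)
    table, truth = simulate_cohort(preset, small_schema, n=120, seed=5)
    return table, truth
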