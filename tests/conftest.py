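import io

import pandas as pd
import pytest

from ttraop import curation
from ttraop.descriptors import descriptor_table
from ttraop.synth import GeneratorSpec, gen_binding_dataset


def records_from_frame(df: pd.DataFrame):
    """Parse a generated binding frame through the real CSV code path."""
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return curation.parse_binding_table(buf)


@pytest.fixture(scope="session")
def binding_default():
    """Default synthetic binding table (salts + duplicate planted) and truth."""
    return gen_binding_dataset(GeneratorSpec(seed=2, exact_duplicate_ec50=1.71))


@pytest.fixture(scope="session")
def curated_actives(binding_default):
    df, _ = binding_default
    records = curation.curate(records_from_frame(df))
    return [r for r in records if r.binder_class != "inactive"]


@pytest.fixture(scope="session")
def active_descriptors(curated_actives):
    """Full 3D descriptor table for the curated actives (computed once)."""
    return descriptor_table([(r.compound_id, r.smiles) for r in curated_actives])
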