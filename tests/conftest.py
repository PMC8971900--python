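import numpy as np
import pandas as pd
import pytest

import oralsite as o


@pytest.fixture
def tiny_table() -> o.FeatureTable:
    data = pd.DataFrame(
        [[5, 1, 0, 3], [0, 0, 2, 7], [4, 0, 0, 1]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3", "f4"],
    )
    return o.FeatureTable(data)


@pytest.fixture
def tiny_metadata() -> o.SampleMetadata:
    data = pd.DataFrame(
        {
            "individual_id": ["i1", "i1", "i2", "i2"],
            "habitat": ["saliva", "buccal_mucosa", "saliva", "buccal_mucosa"],
            "sex": ["F", "F", "M", "M"],
            "age": [31, 31, 44, 44],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return o.SampleMetadata(data)


@pytest.fixture(scope="session")
def small_study():
    """A small paired cohort at default profile settings."""
    cfg = o.SimulationConfig(
        n_individuals=12, reads=(6000, 9000), n_rare_taxa=120, seed=42
    )
    return o.generate_paired_study(cfg)


@pytest.fixture(scope="session")
def prepared_study(small_study):
    table, taxonomy, metadata = small_study
    table = o.remove_singletons(table)
    depth = o.rarefaction_depth(table)
    prepared = o.rarefy(table, depth, seed=1)
    return prepared, taxonomy, metadata.subset(prepared.sample_ids), depth
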