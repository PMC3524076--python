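import numpy as np
import pytest

from fmskit import AbundanceTable, SyntheticSpec, generate


@pytest.fixture
def two_class_table():
    """Small labelled percent-abundance table with known structure."""
    table, truth = generate(
        SyntheticSpec(
            n_per_class=(30, 30),
            n_features=20,
            n_informative=6,
            redundancy_groups=((3, 0.95),),
            sparsity=0.5,
            effect_size=1.5,
            seed=42,
        )
    )
    return table, truth


@pytest.fixture
def default_fixture():
    """The reference two-class redundancy fixture."""
    return generate(SyntheticSpec(seed=7))


def toy_table():
    values = np.array(
        [
            [2.0, 3.0, 5.0],
            [1.0, 1.0, 2.0],
            [10.0, 0.0, 10.0],
            [4.0, 4.0, 2.0],
        ]
    )
    return AbundanceTable(
        values=values,
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_labels=["taxA", "taxB", "taxC"],
        labels=np.array(["x", "x", "y", "y"]),
    )


@pytest.fixture
def small_table():
    return toy_table()
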