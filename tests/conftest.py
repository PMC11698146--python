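import numpy as np
import pytest

from neurosync import (
    NetworkDefinition,
    NetworkSpec,
    SubjectTimeSeries,
    default_config,
    gen_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset: 4/group, 12 units, 60 TRs."""
    cfg = default_config(
        n_per_group=4,
        n_units=12,
        n_tr=60,
        alpha_load=0.6,
        network_spec=(
            NetworkSpec("tom", members=tuple(range(6))),
            NetworkSpec("affective", members=tuple(range(6, 12))),
        ),
        seed=11,
    )
    return gen_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_subjects(arrays, groups=None, tr=3.0):
    """Wrap raw (units x T) arrays as SubjectTimeSeries of one group."""
    groups = groups or ["pmdd"] * len(arrays)
    return [
        SubjectTimeSeries(f"s{i:02d}", g, a, tr_seconds=tr)
        for i, (a, g) in enumerate(zip(arrays, groups))
    ]
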