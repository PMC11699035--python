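import numpy as np
import pandas as pd
import pytest

from immunopheno.events import auto_logicle_transform, merge_samples
from immunopheno.synthetic import (
    SyntheticCohortConfig,
    default_panel,
    default_populations,
    generate_event_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """3 samples x 800 events of the default archetypes (fast)."""
    cfg = SyntheticCohortConfig(
        samples=[("S1", 800, None), ("S2", 800, None), ("S3", 800, None)],
        panel=default_panel(),
        seed=11,
    )
    return generate_event_cohort(cfg, default_populations())


@pytest.fixture(scope="session")
def small_merged(small_cohort):
    """The small cohort auto-logicle-transformed and merged."""
    transformed = [auto_logicle_transform(t)[0] for t in small_cohort]
    return merge_samples(transformed)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_gaussians(rng):
    """Two well-separated (10 SD) Gaussian populations in 4-D.

    Sized so that the default-scale neighbor count (k=60) spans a large
    share of each population and modularity keeps the populations whole.
    """
    a = rng.normal(0.0, 1.0, size=(100, 4))
    b = rng.normal(10.0, 1.0, size=(100, 4))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 100)
    perm = rng.permutation(200)
    return X[perm], labels[perm]
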