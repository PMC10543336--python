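import numpy as np
import pytest

from seedcoex import staging as st
from seedcoex.modules import detect_modules
from seedcoex.simulate import (
    SynthConfig,
    generate_atlas,
    generate_population,
    generate_timecourse,
)


@pytest.fixture(scope="session")
def cfg():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def timecourse(cfg):
    """(ExpressionMatrix with replicates, GeneAnnotation, SynthTruth)."""
    return generate_timecourse(cfg)


@pytest.fixture(scope="session")
def averaged(timecourse):
    em, _, _ = timecourse
    return st.average_replicates(em)


@pytest.fixture(scope="session")
def averaged_log(averaged):
    return st.log_transform(averaged)


@pytest.fixture(scope="session")
def atlas(cfg, averaged, timecourse):
    _, _, truth = timecourse
    return generate_atlas(cfg, averaged, truth)


@pytest.fixture(scope="session")
def network(averaged):
    """Full module-detection result on the default synthetic time course."""
    return detect_modules(averaged)


@pytest.fixture(scope="session")
def population(cfg, timecourse):
    _, _, truth = timecourse
    return generate_population(cfg, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
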