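import numpy as np
import pytest

from hrdcc import StudyConfig, build_tree, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    """One animal, moderate event counts: fast but realistic samples."""
    return StudyConfig(n_animals=1, events_per_sample=20_000)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def trees(small_config):
    return {m: build_tree(m, small_config) for m in ("milk", "blood")}


@pytest.fixture(scope="session")
def blood_sample(small_study):
    row = small_study.samples[(small_study.samples.matrix == "blood")
                              & (small_study.samples.dim > 100)].iloc[0]
    return small_study.events_for(row.sample_id), small_study.states[row.sample_id]


@pytest.fixture(scope="session")
def milk_sample(small_study):
    row = small_study.samples[(small_study.samples.matrix == "milk")
                              & (small_study.samples.dim > 100)].iloc[0]
    return small_study.events_for(row.sample_id), small_study.states[row.sample_id]


@pytest.fixture(scope="session")
def truth_study():
    """Full-size study used at truth level (no event synthesis)."""
    return simulate_study(StudyConfig(), seed=5)


@pytest.fixture(scope="session")
def truth_phase_tables(truth_study):
    """Long-format truth percentages shaped like a gating table."""
    tf = truth_study.truth_frame()
    tf["denominator"] = "parent"
    tf["mode"] = "reference"
    return (tf[["sample_id", "node", "percent", "denominator", "mode"]],
            truth_study.samples, truth_study.biomarkers)
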