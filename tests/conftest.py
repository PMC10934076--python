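import numpy as np
import pytest

from ecgkey import preprocess, synthecg
from ecgkey.keygen import PipelineConfig, PopulationFeatures


@pytest.fixture(scope="session")
def template():
    return synthecg.make_subject(1)


@pytest.fixture(scope="session")
def clean_record(template):
    """Zero-noise 20 s record at 70 bpm with ground-truth fiducials."""
    return synthecg.synth_record(template, session_index=0, duration_s=20.0,
                                 hr_bpm=70.0, noise_cfg="none", rng_seed=5)


@pytest.fixture(scope="session")
def noisy_record(template):
    return synthecg.synth_record(template, session_index=0, duration_s=20.0,
                                 hr_bpm=70.0, noise_cfg="default", rng_seed=5)


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    return preprocess.delineate(preprocess.denoise(clean_record))


@pytest.fixture(scope="session")
def normalized_beats(clean_beats):
    hr = preprocess.observed_heart_rate(clean_beats)
    return preprocess.normalize_beats(clean_beats, hr)


@pytest.fixture(scope="session")
def population_records():
    return synthecg.synth_population(20, rng_seed=77)


@pytest.fixture(scope="session")
def population_features(population_records):
    return PopulationFeatures.from_records(population_records)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()
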