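import numpy as np
import pytest

from frailsense import pipeline
from frailsense import synthetic_data as syn


@pytest.fixture(scope="session")
def default_schedule():
    return syn.sample_schedule(syn.SubjectProfile(subject_id="S_default"), seed=11)


@pytest.fixture(scope="session")
def default_recording(default_schedule):
    return syn.render_signal(default_schedule, seed=12)


@pytest.fixture(scope="session")
def default_result(default_recording):
    return pipeline.process_recording(default_recording)


@pytest.fixture(scope="session")
def gapped_subject():
    """Subject with a programmed 95-min non-wear gap in the afternoon of day 2."""
    profile = syn.SubjectProfile(subject_id="S_gap", nonwear_gaps=((44 * 3600, 95),))
    schedule = syn.sample_schedule(profile, seed=21)
    rec = syn.render_signal(schedule, seed=22)
    return schedule, pipeline.process_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
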