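import numpy as np
import pytest
from hypothesis import settings

from volcurves.cohort import SubjectRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_subject(
    subject_id="S1",
    age=65.0,
    gender="female",
    abeta42=1500.0,
    ttau=200.0,
    ptau=20.0,
    fazekas=0,
    microbleeds=0,
    stroke_history=False,
    cdr_global=0.0,
    qc_pass=True,
    radiological_exclusion=False,
    tiv=1450.0,
    volumes=None,
) -> SubjectRecord:
    """A fully negative, fully included subject unless overridden."""
    return SubjectRecord(
        subject_id=subject_id,
        age=age,
        gender=gender,
        abeta42=abeta42,
        ttau=ttau,
        ptau=ptau,
        fazekas=fazekas,
        microbleeds=microbleeds,
        stroke_history=stroke_history,
        cdr_global=cdr_global,
        qc_pass=qc_pass,
        radiological_exclusion=radiological_exclusion,
        tiv=tiv,
        volumes=volumes if volumes is not None else {"R1": 7.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
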