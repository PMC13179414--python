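import numpy as np
import pytest

from winodds import SubjectRecord


def make_record(
    subject_id=0,
    arm=0,
    covariates=(),
    terminal_time=10.0,
    terminal_event=0,
    nonfatal_time=None,
    nonfatal_event=0,
):
    """Compact SubjectRecord builder with the no-nonfatal default."""
    if nonfatal_time is None:
        nonfatal_time = terminal_time
    return SubjectRecord(
        subject_id=subject_id,
        arm=arm,
        covariates=np.asarray(covariates, dtype=float),
        terminal_time=terminal_time,
        terminal_event=terminal_event,
        nonfatal_time=nonfatal_time,
        nonfatal_event=nonfatal_event,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
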