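import numpy as np
import pytest

from eegstages.core import QCStatus, Segment, SessionMeta, emotiv_montage


@pytest.fixture(scope="session")
def montage():
    return emotiv_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_segment(montage):
    """Wrap a channels x samples array into a Segment with chosen QC state."""

    def factory(data, fs=128.0, qc=QCStatus.KEPT, subject="T01", session=1,
                task="lecture", index=0):
        return Segment(
            data=np.asarray(data, float), fs=fs, montage=montage,
            meta=SessionMeta(subject, session, task),
            index=index, start_sample=0, qc=qc)

    return factory
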