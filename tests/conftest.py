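import numpy as np
import pytest

from seqdsn.sequence_io import SiteRecord, TranscriptSet


@pytest.fixture
def tiny_transcripts() -> TranscriptSet:
    ts = TranscriptSet()
    ts.add("t1", "AAUAA")
    ts.add("t2", "UAA")
    ts.add("t3", "ACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUA")
    return ts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_site(tid="t1", pos=2, label=1, domain="source", tags=()):
    return SiteRecord(tid, pos, label, domain, tuple(tags))


@pytest.fixture
def site_factory():
    return make_site
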