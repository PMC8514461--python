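import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plantmeth.preprocess import EventAlignedRead

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_read(
    rng: np.random.Generator,
    chrom: str = "c1",
    strand: str = "+",
    start: int = 0,
    length: int = 40,
    read_id: str = "r1",
    max_signals: int = 6,
) -> EventAlignedRead:
    bases = "".join(rng.choice(list("ACGT"), size=length))
    signals = [
        rng.normal(0, 1, size=int(rng.integers(1, max_signals + 1))).tolist()
        for _ in range(length)
    ]
    return EventAlignedRead(
        read_id=read_id, chrom=chrom, strand=strand, start=start, bases=bases, signals=signals
    )


@pytest.fixture
def make_read():
    return random_read
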