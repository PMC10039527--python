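import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plasmidcheck import SequencedRead, TemplateSequence, make_reference

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def as_read(sequence: str, read_id: str = "r", quality: int = 20) -> SequencedRead:
    return SequencedRead(
        read_id=read_id,
        sequence=sequence,
        qualities=np.full(len(sequence), quality, dtype=np.int16),
    )


@pytest.fixture(scope="session")
def template_1k() -> TemplateSequence:
    """1 kb random template with one embedded 12-mer homopolymer."""
    return make_reference(1000, seed=101, homopolymer_runs=[(500, "A", 12)])


@pytest.fixture(scope="session")
def template_600() -> TemplateSequence:
    return make_reference(600, seed=7)
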