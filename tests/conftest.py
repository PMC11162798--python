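import pytest
from hypothesis import settings

from repstab.ce_sizing import SizingModel
from repstab.read_counter import AnchorSpec
from repstab.synthetic_data import synthetic_flanks

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def g4c2_model() -> SizingModel:
    return SizingModel()


@pytest.fixture(scope="session")
def flanks() -> tuple[str, str]:
    return synthetic_flanks()


@pytest.fixture(scope="session")
def anchors(flanks) -> AnchorSpec:
    prefix, suffix = flanks
    return AnchorSpec(prefix_seq=prefix[-150:], suffix_seq=suffix[:150])
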