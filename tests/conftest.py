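import pytest
from hypothesis import settings

from pvpmap.simulate import SyntheticConfig, simulate_landscape

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_landscape():
    """The default study conditions: 10-Mb chromosome, 20 planted enhancers."""
    return simulate_landscape(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_track(default_landscape):
    from pvpmap.core import ReadTrack

    return ReadTrack.from_reads(default_landscape.reads["H3K27ac"])


@pytest.fixture(scope="session")
def truth_records(default_landscape):
    """Planted enhancers as map records (ground truth, not pipeline output)."""
    from pvpmap.mapbuild import EnhancerRecord

    return [
        EnhancerRecord(
            interval=e.core, pvp=True, supporting_tf_sets=frozenset(e.tf_labels),
            provenance="truth",
        )
        for e in default_landscape.enhancers
    ]
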