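import numpy as np
import pytest
from hypothesis import settings

from osteoid import synth

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reference():
    """A 3 kb random mtDNA-like reference (small for speed)."""
    return synth.random_reference(3000, seed=1)


@pytest.fixture(scope="session")
def fixture_tree(reference):
    """The fictional ~25-node defining-variant tree built on `reference`."""
    return synth.build_fixture_tree(reference, seed=17)


@pytest.fixture
def sam_file(tmp_path):
    """Factory writing simulated reads to a SAM file, returning its path."""

    def write(spec: synth.ReadSimSpec, name: str = "reads.sam"):
        sam, truth = synth.simulate_reads(spec)
        path = tmp_path / name
        path.write_text(sam)
        return path, truth

    return write
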