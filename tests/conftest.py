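import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sozloc.io_formats import PipelineConfig
from sozloc.phantom import PhantomSpec, generate_anatomy, generate_subject


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_spec():
    """A small but geometrically faithful phantom subject spec."""
    return PhantomSpec(n_ics=12, seed=7)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_subject(small_spec)


@pytest.fixture(scope="session")
def anatomy(small_spec):
    return generate_anatomy(small_spec)
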