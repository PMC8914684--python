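import pytest

from maternshape import generate_synthetic_avatars


@pytest.fixture(scope="session")
def avatars():
    """One shared synthetic avatar set (anchors verified at build)."""
    return generate_synthetic_avatars(resolution=40, seed=1)

from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
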