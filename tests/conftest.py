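import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from amoascan.primers import load_packaged_primer_sets  # noqa: E402
from amoascan.simulate import make_reference_panel  # noqa: E402


@pytest.fixture(scope="session")
def mixtures():
    return load_packaged_primer_sets()


@pytest.fixture(scope="session")
def small_panel():
    """3 genes per clade, 2% within-clade divergence, fixed seed."""
    return make_reference_panel(n_per_clade=3, within_clade_divergence=0.02, seed=11)
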