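import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_alignment():
    """Six samples, three demes, small but non-trivial variation."""
    from paleoabc.data import HeterochronousAlignment, SequenceSample

    base = "ACGT" * 10
    variant = "ACGT" * 9 + "ACGA"
    return HeterochronousAlignment(
        [
            SequenceSample("e1", base, 4000.0, "europe"),
            SequenceSample("e2", variant, 12000.0, "europe"),
            SequenceSample("s1", base, 8000.0, "siberia"),
            SequenceSample("s2", base, 30000.0, "siberia"),
            SequenceSample("a1", variant, 5000.0, "america", clade="I"),
            SequenceSample("a2", variant, 60000.0, "america", clade="I"),
        ]
    )
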