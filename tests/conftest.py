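import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_genome(rng, length, gc=0.4, circular=False, id="g"):
    from mitorepeats import Genome

    p_gc = gc / 2
    p_at = (1 - gc) / 2
    seq = "".join(
        rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    )
    return Genome(id=id, sequence=seq, circular=circular)
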