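import logging

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# generator warnings (dangling drugs etc.) are expected on synthetic fixtures
logging.getLogger("herbnetpharm").setLevel(logging.ERROR)


@pytest.fixture
def toy_network():
    """The worked diffusion example: s1->{d1,d2}, s2->{d1}; d1->{t1,t2}, d2->{t2}."""
    from herbnetpharm.sdtnbi import SDTNetwork

    return SDTNetwork(
        drug_target_edges=[("d1", "t1"), ("d1", "t2"), ("d2", "t2")],
        substructure_drug_edges=[("s1", "d1"), ("s1", "d2"), ("s2", "d1")],
    )
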