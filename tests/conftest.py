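import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_otu_table():
    from soiltox.model import OtuTable

    return OtuTable(
        otu_ids=["OTU1", "OTU2", "OTU3"],
        lineages=[
            ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Hyphomicrobiaceae", "Devosia"),
            ("Proteobacteria", "Alphaproteobacteria", "", "", ""),
            ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
        ],
        samples=["S1", "S2"],
        counts=np.array([[60, 10], [25, 40], [15, 50]]),
    )
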