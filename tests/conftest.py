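import pytest
from hypothesis import HealthCheck, settings

from padds.merging import DomainAnnotation

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def worked_example_annotations():
    """The seven multi-database annotations of the yeast formin BNI1
    (YNL271C): four PFAM records (FH2, Drf_FH3, two tandem Drf_GBD
    copies), two Superfamily records (the formin-homology-2 domain,
    co-located with FH2, and an ARM repeat spanning the Drf_FH3/Drf_GBD
    region) and one SMART record (Formin Homology, co-located with FH2).
    """
    A = DomainAnnotation
    return [
        A("YNL271C", "PFAM", "FH2", 1250, 1650),
        A("YNL271C", "PFAM", "Drf_FH3", 450, 800),
        A("YNL271C", "PFAM", "Drf_GBD", 90, 260),
        A("YNL271C", "PFAM", "Drf_GBD", 300, 430),
        A("YNL271C", "SF", "Formin homology 2 domain (FH2 domain)", 1240, 1660),
        A("YNL271C", "SF", "ARM repeat", 100, 820),
        A("YNL271C", "SMART", "Formin Homology", 1255, 1640),
    ]


@pytest.fixture
def worked_example_proteome():
    return {"YNL271C": 1953}
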