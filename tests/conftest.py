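import pytest
from hypothesis import HealthCheck, settings

import strclone as sc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel() -> sc.LocusPanel:
    return sc.load_panel()


@pytest.fixture(scope="session")
def jurkat() -> sc.STRProfile:
    return sc.reference_profile("JURKAT", "OWN")


@pytest.fixture(scope="session")
def wil2s() -> sc.STRProfile:
    return sc.reference_profile("WIL2S", "OWN")


def child_of(parent: sc.STRProfile, clone_id="child", amelo_y=None, **loci):
    """Copy of ``parent`` with designated loci replaced by allele strings."""
    calls = dict(parent.calls)
    for locus, text in loci.items():
        calls[locus] = sc.parse_allele_set(text)
    return sc.STRProfile(
        clone_id=clone_id,
        calls=calls,
        amelo_x=parent.amelo_x,
        amelo_y=parent.amelo_y if amelo_y is None else amelo_y,
    )
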