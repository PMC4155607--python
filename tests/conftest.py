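import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from seqbundles import Alignment, assign_groups, single_group


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Three 4-column rows with a gap, consensus PPKK."""
    return Alignment(("a", "b", "c"), ("PPKK", "PPK-", "PP-K"))


@pytest.fixture
def tiny_grouped(tiny_alignment):
    return single_group(tiny_alignment)


@pytest.fixture
def two_group_alignment():
    """Five rows split into two labelled groups."""
    aln = Alignment(
        ("p1", "p2", "p3", "n1", "n2"),
        ("ACDKA", "ACDKA", "AC-KV", "GCDKA", "GCDFA"),
    )
    return assign_groups(
        aln,
        [("pos", "#000000", [0, 1, 2]), ("neg", "#33A6E6", [3, 4])],
    )


@pytest.fixture(scope="session")
def contest_fixture():
    """The contest-scale stand-in dataset, generated once per session."""
    from seqbundles import contest_like

    return contest_like(1)
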