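import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vitacap.knowledge import (
    CobalaminUtilizationLists,
    FunctionalRole,
    KnowledgeBase,
    PathwayVariant,
    default_knowledge_base,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_kb():
    return default_knowledge_base()


@pytest.fixture()
def tiny_kb():
    """Two-vitamin KB: thiamine with two branches, tri-segment cobalamin."""
    roles = (
        FunctionalRole("t1", "THI", frozenset({"K00001"})),
        FunctionalRole("t2a", "THI", frozenset({"K00002"})),
        FunctionalRole("t2b", "THI", frozenset({"K00003", "K00004"})),
        FunctionalRole("c_an1", "COB", frozenset({"K00010"})),
        FunctionalRole("c_an2", "COB", frozenset({"K00011"})),
        FunctionalRole("c_ae1", "COB", frozenset({"K00012"})),
        FunctionalRole("c_post", "COB", frozenset({"K00013"})),
    )
    variants = (
        PathwayVariant("THI_a", "THI", ("t1", "t2a"), frozenset({"t1", "t2a"}), "a"),
        PathwayVariant("THI_b", "THI", ("t1", "t2b"), frozenset({"t1", "t2b"}), "b"),
        PathwayVariant("COB_an", "COB", ("c_an1", "c_an2"),
                       frozenset({"c_an1", "c_an2"}), "anaerobic"),
        PathwayVariant("COB_ae", "COB", ("c_ae1",), frozenset({"c_ae1"}), "aerobic"),
        PathwayVariant("COB_post", "COB", ("c_post",), frozenset({"c_post"}),
                       "post_cobyrinate"),
    )
    util = CobalaminUtilizationLists(
        transporter_roles={"btuB": frozenset({"K00020"})},
        dependent_enzyme_roles={"metH": frozenset({"K00021"})},
    )
    return KnowledgeBase("tiny-test-kb", roles, variants, util)


@pytest.fixture()
def two_gene_counts():
    """The worked 2-gene TPM fixture: counts (9, 1), lengths (3000, 1000)."""
    counts = pd.DataFrame({"s1": [9, 1]}, index=["gA", "gB"])
    counts.index.name = "gene_id"
    return counts
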