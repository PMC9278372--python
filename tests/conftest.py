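import pytest
from hypothesis import settings

from gcea import InterventionScenario, Platform, ProgrammeCluster

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_scenario(
    sid,
    cost,
    hly,
    programme="prog-a",
    platform=Platform.FIRST_LEVEL_CLINICAL,
    group=None,
    name=None,
):
    return InterventionScenario(
        id=sid,
        name=name or sid,
        programme=programme,
        platform=platform,
        cost_pv=cost,
        hly=hly,
        exclusivity_group=group,
    )


def make_cluster(programme, scenarios, fixed=0.0, combinations=None):
    return ProgrammeCluster(
        programme=programme,
        scenarios=tuple(scenarios),
        fixed_support_cost=fixed,
        combinations=combinations or {},
    )


@pytest.fixture
def scenario_factory():
    return make_scenario


@pytest.fixture
def cluster_factory():
    return make_cluster


@pytest.fixture
def abc_clusters():
    """Three independent single-scenario programmes: A(100,10), B(200,15),
    C(150,8). C costs more and gains less health than A."""
    return [
        make_cluster("prog-a", [make_scenario("A", 100, 10, "prog-a")]),
        make_cluster("prog-b", [make_scenario("B", 200, 15, "prog-b")]),
        make_cluster("prog-c", [make_scenario("C", 150, 8, "prog-c")]),
    ]
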