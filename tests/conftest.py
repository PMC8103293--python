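import numpy as np
import pytest

from sensortoy.cube import build_topology
from sensortoy.games import (
    enumerate_roadrunner_permutations,
    maze_schedule,
    roadrunner_schedule,
)
from sensortoy.players import ChildProfile, skill_to_percentile


@pytest.fixture(scope="session")
def topo():
    return build_topology()


@pytest.fixture(scope="session")
def rr_schedule():
    return roadrunner_schedule(enumerate_roadrunner_permutations()[1])


@pytest.fixture(scope="session")
def maze_sched():
    return maze_schedule()


def make_child(skill: float, *, id: str = "t0", age: float = 7.8,
               gender: str = "girl", activity: float = 1.0) -> ChildProfile:
    pct = skill_to_percentile(skill)
    return ChildProfile(id=id, age=age, gender=gender, skill=skill,
                        percentile=pct, label=int(pct <= 16),
                        control_skill=skill, activity=activity)


@pytest.fixture(scope="session")
def mid_child():
    return make_child(0.6)
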