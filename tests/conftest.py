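import pytest
from hypothesis import settings

from cofoldviz import generate_fixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

MINIMAL_TRAJECTORY = """\
id time occupancy structure energy
0 0.1 1.0 .... -0.0
"""

COMPETITION_TRAJECTORY = """\
# two competing hairpins on a growing transcript
id time occupancy structure energy
0 0.5 1.0 ((....)) -3.0
0 1.0 0.7 (((....))). -5.0
1 1.0 0.3 .((....)).. -4.0
1 2.0 0.8 .(((....))). -6.5
0 2.0 0.15 ((((....)))) -6.0
2 2.0 0.05 ............ 0.0
1 10.0 0.9 .(((....))). -6.5
0 10.0 0.1 ((((....)))) -6.0
"""


@pytest.fixture
def minimal_text():
    return MINIMAL_TRAJECTORY


@pytest.fixture
def competition_text():
    return COMPETITION_TRAJECTORY


@pytest.fixture
def competition_traj(competition_text):
    from cofoldviz import parse_trajectory

    return parse_trajectory(competition_text)


@pytest.fixture
def helix_competition():
    return generate_fixture("helix-competition", seed=1, n_timepoints=12, final_length=30)
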