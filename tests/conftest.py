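import numpy as np
import pytest

from endonet import ParameterSet
from endonet.fixed_points import enumerate_fixed_points, sample_attractors
from endonet import synthetic as syn


@pytest.fixture(scope="session")
def toggle_net():
    return syn.make_toggle_switch()


@pytest.fixture(scope="session")
def toggle_self_net():
    return syn.make_toggle_switch(with_self_activation=True)


@pytest.fixture(scope="session")
def self_net():
    return syn.make_self_activator()


@pytest.fixture(scope="session")
def mini_net():
    return syn.make_miniature_fate_network()


@pytest.fixture(scope="session")
def ring_net():
    return syn.make_inhibition_ring()


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet.global_params()


@pytest.fixture(scope="session")
def toggle_attractors(toggle_net):
    return sample_attractors(toggle_net, None, n_starts=200, seed=1)


@pytest.fixture(scope="session")
def toggle_fps(toggle_net):
    return enumerate_fixed_points(toggle_net, None, n_seeds=100, seed=1,
                                  n_starts=100)


@pytest.fixture(scope="session")
def mini_attractors(mini_net):
    return sample_attractors(mini_net, None, n_starts=300, seed=1)


@pytest.fixture(scope="session")
def mini_fps(mini_net, mini_attractors):
    return enumerate_fixed_points(mini_net, None, n_seeds=300, seed=2,
                                  attractors=mini_attractors)


def attractor_id_by_profile(att, predicate):
    """First attractor id whose discretized profile satisfies predicate."""
    for aid, fp in zip(att.ids, att.points):
        if predicate(fp.profile()):
            return aid
    raise AssertionError("no attractor matches the requested profile")
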