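import itertools

import numpy as np
import pytest

from endonet.perturbation import (PerturbationProtocol, Stage, apply_protocol,
                                  perturbation_screen, switch_experiment)

from conftest import attractor_id_by_profile


@pytest.fixture(scope="module")
def a_high(toggle_attractors):
    return attractor_id_by_profile(toggle_attractors, lambda p: p == (1, 0))


@pytest.fixture(scope="module")
def b_high(toggle_attractors):
    return attractor_id_by_profile(toggle_attractors, lambda p: p == (0, 1))


class TestProtocols:
    def test_empty_protocol_is_identity(self, toggle_net, toggle_attractors,
                                        a_high):
        start = toggle_attractors.by_id(a_high).state
        res = apply_protocol(toggle_net, None, start,
                             PerturbationProtocol(stages=[]),
                             toggle_attractors)
        assert res.end_attractor == a_high
        assert not res.switched

    def test_single_stage_switches_toggle(self, toggle_net,
                                          toggle_attractors, a_high, b_high):
        res = switch_experiment(toggle_net, None, a_high, {"B": 1.0},
                                duration=10.0, attractors=toggle_attractors)
        assert res.start_attractor == a_high
        assert res.end_attractor == b_high
        assert res.switched

    def test_full_clamp_jump_crosses_separatrix_at_any_dwell(
            self, toggle_net, toggle_attractors, a_high, b_high):
        # clamping is jump-and-hold: setting B=1 instantly places the state
        # across the toggle's diagonal separatrix, so even a vanishing dwell
        # commits the switch
        res = switch_experiment(toggle_net, None, a_high, {"B": 1.0},
                                duration=0.01, attractors=toggle_attractors)
        assert res.end_attractor == b_high

    def test_partial_clamp_shows_dwell_time_dependence(
            self, toggle_net, toggle_attractors, a_high, b_high):
        # a clamp below the separatrix only switches if held long enough
        # for the free node to decay past it
        short = switch_experiment(toggle_net, None, a_high, {"B": 0.6},
                                  duration=0.1, attractors=toggle_attractors)
        long = switch_experiment(toggle_net, None, a_high, {"B": 0.6},
                                 duration=5.0, attractors=toggle_attractors)
        assert short.end_attractor == a_high
        assert long.end_attractor == b_high

    def test_determinism(self, toggle_net, toggle_attractors, a_high):
        r1 = switch_experiment(toggle_net, None, a_high, {"B": 1.0},
                               attractors=toggle_attractors)
        r2 = switch_experiment(toggle_net, None, a_high, {"B": 1.0},
                               attractors=toggle_attractors)
        assert r1.end_attractor == r2.end_attractor
        assert np.array_equal(r1.trajectory.states, r2.trajectory.states)

    def test_unknown_clamp_node_raises(self, toggle_net, toggle_attractors,
                                       a_high):
        with pytest.raises(Exception):
            switch_experiment(toggle_net, None, a_high, {"Z": 1.0},
                              attractors=toggle_attractors)

    def test_staged_protocol_records_intermediates(self, mini_net,
                                                   mini_attractors):
        fate_a = attractor_id_by_profile(mini_attractors,
                                         lambda p: p[0] == 1)
        apoptotic = attractor_id_by_profile(
            mini_attractors, lambda p: p[-1] == 1 and p[0] == 0)
        protocol = PerturbationProtocol(stages=[
            Stage(clamps={"FateA": 0.0}, duration=30.0),
            Stage(clamps={"Apop": 1.0}, duration=30.0),
        ])
        start = mini_attractors.by_id(fate_a).state
        res = apply_protocol(mini_net, None, start, protocol, mini_attractors)
        assert res.start_attractor == fate_a
        assert res.end_attractor == apoptotic
        assert len(res.intermediate_attractors) == 1

    def test_trajectory_time_is_cumulative(self, toggle_net,
                                           toggle_attractors, a_high):
        res = switch_experiment(toggle_net, None, a_high, {"B": 1.0},
                                duration=5.0, attractors=toggle_attractors)
        assert np.all(np.diff(res.trajectory.times) >= 0)
        assert res.trajectory.times[-1] > 5.0  # clamp stage + relaxation

    def test_yaml_round_trip(self):
        protocol = PerturbationProtocol(stages=[
            Stage(clamps={"SHH": 0.0, "Runx1": 1.0, "BMP": 1.0},
                  duration=40.0)])
        back = PerturbationProtocol.from_yaml(protocol.to_yaml())
        assert back == protocol


class TestScreen:
    def test_toggle_screen_matches_brute_force(self, toggle_net,
                                               toggle_attractors,
                                               a_high, b_high):
        hits = perturbation_screen(toggle_net, None, a_high, b_high,
                                   max_set_size=1,
                                   attractors=toggle_attractors)
        # independent brute force over every (node, level) single clamp
        expected = []
        for node in sorted(toggle_net.node_names):
            for level in (0.0, 1.0):
                res = switch_experiment(toggle_net, None, a_high,
                                        {node: level},
                                        attractors=toggle_attractors)
                if res.end_attractor == b_high:
                    expected.append({node: level})
        assert hits == expected
        assert {frozenset(h.items()) for h in hits} == {
            frozenset({("A", 0.0)}), frozenset({("B", 1.0)})}

    def test_unreachable_target_yields_empty(self, toggle_net,
                                             toggle_attractors, a_high):
        hits = perturbation_screen(toggle_net, None, a_high, "A9",
                                   max_set_size=1,
                                   attractors=toggle_attractors)
        assert hits == []

    def test_mini_fate_switch_found_within_two_clamps(self, mini_net,
                                                      mini_attractors):
        fate_a = attractor_id_by_profile(mini_attractors,
                                         lambda p: p[0] == 1)
        fate_b = attractor_id_by_profile(mini_attractors,
                                         lambda p: p[1] == 1)
        hits = perturbation_screen(
            mini_net, None, fate_a, fate_b, max_set_size=2,
            candidate_nodes=["FateA", "FateB", "Apop"],
            attractors=mini_attractors)
        assert hits
        assert all(len(h) <= 2 for h in hits)
        assert {"FateB": 1.0} in hits
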