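"""Clamp-and-release switching protocols between attractors.

An induced switch models a drug or genetic intervention: selected node
activities are held ("clamped") at fixed values for a dwell time, driving
the state across a basin boundary, then released so the free dynamics
relaxes into whichever attractor's basin the state landed in.  Protocols
may chain several stages (sequential interventions); a screen searches
clamp sets of increasing size for the minimal interventions that realize a
desired attractor-to-attractor switch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dynamics import CompiledDynamics, ParameterSet, Trajectory, integrate, relax
from .fixed_points import AttractorSet
from .network import Network

STAGE_DURATION = 50.0


@dataclass
class Stage:
    clamps: dict[str, float]
    duration: float = STAGE_DURATION

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stage duration must be positive")


@dataclass
class PerturbationProtocol:
    stages: list[Stage]
    release_between: bool = True

    @classmethod
    def single(cls, clamps: dict[str, float],
               duration: float = STAGE_DURATION) -> "PerturbationProtocol":
        return cls(stages=[Stage(clamps=dict(clamps), duration=duration)])

    @classmethod
    def from_yaml(cls, text: str) -> "PerturbationProtocol":
        doc = yaml.safe_load(text)
        stages = [Stage(clamps={str(k): float(v) for k, v in d["clamps"].items()},
                        duration=float(d.get("duration", STAGE_DURATION)))
                  for d in doc["stages"]]
        return cls(stages=stages,
                   release_between=bool(doc.get("release_between", True)))

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "release_between": self.release_between,
            "stages": [{"clamps": st.clamps, "duration": st.duration}
                       for st in self.stages]})


@dataclass
class SwitchResult:
    start_attractor: str
    end_attractor: str                    # attractor id or "none"
    trajectory: Trajectory
    intermediate_attractors: list[str] = field(default_factory=list)

    @property
    def switched(self) -> bool:
        return (self.end_attractor != "none"
                and self.end_attractor != self.start_attractor)


def _identify(attractors: AttractorSet, state) -> str:
    m = attractors.match(state)
    return attractors.ids[m] if m is not None else "none"


def apply_protocol(net: Network, params: ParameterSet | None, start,
                   protocol: PerturbationProtocol, attractors: AttractorSet,
                   relax_horizon: float = 100.0, tol: float = 1e-6
                   ) -> SwitchResult:
    """Run a staged clamp protocol from ``start`` (at or near an attractor).

    Each stage clamps its nodes for its duration; between stages (and at
    the end) the clamps release and the free dynamics relaxes to
    convergence.  The attractor reached after each relaxation is recorded.
    """
    dyn = CompiledDynamics(net, params)
    x = np.asarray(start, dtype=float).copy()
    start_id = _identify(attractors, x)
    times = [np.array([0.0])]
    states = [x[None, :]]
    t_off = 0.0

    def _append(traj: Trajectory):
        nonlocal t_off, x
        times.append(traj.times + t_off)
        states.append(traj.states)
        t_off += traj.times[-1]
        x = np.clip(traj.final_state, 0.0, 1.0)

    intermediates: list[str] = []
    end_id = start_id
    for k, stage in enumerate(protocol.stages):
        _append(integrate(net, params, x, stage.duration, clamps=stage.clamps,
                          dynamics=dyn))
        release = protocol.release_between or k == len(protocol.stages) - 1
        if release:
            traj = integrate(net, params, x, relax_horizon,
                             converge_tol=tol, dynamics=dyn)
            _append(traj)
            converged = bool(np.max(np.abs(dyn.rhs(x))) < tol)
            end_id = _identify(attractors, x) if converged else "none"
            if k < len(protocol.stages) - 1:
                intermediates.append(end_id)
    trajectory = Trajectory(times=np.concatenate(times),
                            states=np.concatenate(states, axis=0))
    return SwitchResult(start_attractor=start_id, end_attractor=end_id,
                        trajectory=trajectory,
                        intermediate_attractors=intermediates)


def switch_experiment(net: Network, params: ParameterSet | None,
                      from_attractor: str, clamps: dict[str, float],
                      duration: float = STAGE_DURATION,
                      attractors: AttractorSet | None = None,
                      **kwargs) -> SwitchResult:
    """Single-stage convenience wrapper over :func:`apply_protocol`."""
    if attractors is None:
        raise ValueError("switch_experiment requires the known AttractorSet")
    start = attractors.by_id(from_attractor).state
    protocol = PerturbationProtocol.single(clamps, duration=duration)
    return apply_protocol(net, params, start, protocol, attractors, **kwargs)


def perturbation_screen(net: Network, params: ParameterSet | None,
                        from_attractor: str, to_attractor: str,
                        max_set_size: int = 2,
                        candidate_nodes: list[str] | None = None,
                        duration: float = STAGE_DURATION,
                        attractors: AttractorSet | None = None,
                        all_sizes: bool = False
                        ) -> list[dict[str, float]]:
    """Exhaustive search for minimal clamp sets realizing a switch.

    Tests clamp sets of size 1, 2, ... up to ``max_set_size``; each chosen
    node is clamped to 0 or 1 (full suppression/activation).  Search order
    is size-ascending, then lexicographic in node names and levels, so
    results are reproducible.  Returns all successful sets of the smallest
    successful size (all sizes up to the max with ``all_sizes``); empty
    list if nothing succeeds.
    """
    if attractors is None:
        raise ValueError("perturbation_screen requires the known AttractorSet")
    if max_set_size < 1:
        raise ValueError("max_set_size must be >= 1")
    names = sorted(candidate_nodes if candidate_nodes is not None
                   else net.node_names)
    for nm in names:
        if nm not in net:
            raise KeyError(f"candidate node {nm!r} not in network")
    hits: list[dict[str, float]] = []
    for size in range(1, max_set_size + 1):
        for combo in itertools.combinations(names, size):
            for levels in itertools.product((0.0, 1.0), repeat=size):
                clamps = dict(zip(combo, levels))
                res = switch_experiment(net, params, from_attractor, clamps,
                                        duration=duration,
                                        attractors=attractors)
                if res.end_attractor == to_attractor:
                    hits.append(clamps)
        if hits and not all_sizes:
            return hits
    return hits
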