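"""Fixture generators: networks with known attractor structure and
synthetic expression call tables.

These motifs carry the package's oracle tests: the 1-node self-activator
(three fixed points on the interval, solvable by root scan), the 2-node
toggle switch (the canonical mutual-suppression bistable motif; two
mirror-image attractors separated by one saddle), a 3-node inhibition ring
(oscillatory), a frozen ~8-node miniature fate network (two mutually
suppressing fate hubs with downstream target modules plus a
survival/apoptosis toggle, echoing proliferating / differentiated /
apoptotic attractor families), and seeded random signed networks.  All
generators are pure functions of their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .network import ACTIVATION, INHIBITION, Edge, Network, Node, parse_network
from .profiles import ACTIVE, DOWN, FLAT, UP, DiscreteProfile

CALLS = (UP, DOWN, FLAT)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str          # self_activator | toggle_switch | inhibition_ring |
                       # miniature_fate_network | random_signed
    size: int = 0
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec) -> Network:
    if spec.kind == "self_activator":
        return make_self_activator(**spec.params)
    if spec.kind == "toggle_switch":
        return make_toggle_switch(**spec.params)
    if spec.kind == "inhibition_ring":
        return make_inhibition_ring(n_nodes=spec.size or 3, **spec.params)
    if spec.kind == "miniature_fate_network":
        return make_miniature_fate_network(seed=spec.seed)
    if spec.kind == "random_signed":
        return make_random_signed_network(n_nodes=spec.size, seed=spec.seed,
                                          **spec.params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_self_activator(n: float | None = None, a: float | None = None) -> Network:
    """One node with a single self-activation edge.

    At defaults (n=3, a=0.5) the 1-D system x' = x^n/(a^n+x^n) - x has
    three fixed points: stable 0, unstable threshold, stable high state.
    """
    return Network(nodes=[Node("A", "default")],
                   edges=[Edge("A", "A", ACTIVATION, n=n, a=a)],
                   modules=["default"])


def make_toggle_switch(n: float | None = None, a: float | None = None,
                       with_self_activation: bool = False) -> Network:
    """Two mutually inhibiting nodes, optionally each self-activating.

    The plain toggle at defaults is bistable: two mirror attractors and
    one symmetric saddle.  With self-activation the quiescent (0,0) state
    becomes a third attractor.
    """
    nodes = [Node("A", "default"), Node("B", "default")]
    edges = [Edge("B", "A", INHIBITION, n=n, a=a),
             Edge("A", "B", INHIBITION, n=n, a=a)]
    if with_self_activation:
        edges = [Edge("A", "A", ACTIVATION, n=n, a=a),
                 Edge("B", "B", ACTIVATION, n=n, a=a)] + edges
    return Network(nodes=nodes, edges=edges, modules=["default"])


def make_inhibition_ring(n_nodes: int = 3, n: float | None = None,
                         a: float | None = None) -> Network:
    """Cyclic chain of inhibitions (repressilator-like for odd lengths)."""
    if n_nodes < 2:
        raise ValueError("ring needs at least 2 nodes")
    names = [f"N{i + 1}" for i in range(n_nodes)]
    nodes = [Node(nm, "default") for nm in names]
    edges = [Edge(names[i], names[(i + 1) % n_nodes], INHIBITION, n=n, a=a)
             for i in range(n_nodes)]
    return Network(nodes=nodes, edges=edges, modules=["default"])


def make_miniature_fate_network(seed: int = 0) -> Network:
    """Frozen ~8-node caricature of a cell-fate decision network.

    Wiring ships as a versioned data file so its oracle-computed
    fixed-point census can be hard-coded in tests.  ``seed`` is accepted
    for interface uniformity; the wiring is fixed.
    """
    text = resources.files("endonet.data").joinpath("mini_fate.tsv").read_text()
    return parse_network(text, dialect="tsv")


def make_random_signed_network(n_nodes: int, mean_in_degree: float = 2.0,
                               inhibition_fraction: float = 0.3,
                               seed: int = 0,
                               allow_sources: bool = False) -> Network:
    """Random signed directed network, reproducible from ``seed``.

    In-degrees are Poisson around the mean (floored at 1 unless
    ``allow_sources``); regulator sets are drawn without replacement so no
    (source, target, sign) triple repeats; signs are i.i.d. with the given
    inhibition fraction.  Self-edges are permitted.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 <= inhibition_fraction <= 1:
        raise ValueError("inhibition_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"G{i + 1}" for i in range(n_nodes)]
    nodes = [Node(nm, "default") for nm in names]
    edges: list[Edge] = []
    for tgt in names:
        k = int(rng.poisson(mean_in_degree))
        if not allow_sources:
            k = max(k, 1)
        k = min(k, n_nodes)
        sources = rng.choice(n_nodes, size=k, replace=False)
        for s in sources:
            sign = INHIBITION if rng.random() < inhibition_fraction else ACTIVATION
            edges.append(Edge(names[int(s)], tgt, sign))
    return Network(nodes=nodes, edges=edges, modules=["default"])


def true_diff_calls(profile_before: DiscreteProfile,
                    profile_after: DiscreteProfile) -> list[str]:
    """Up/down/flat implied by an ordered pair of discrete profiles."""
    calls = []
    for b, a in zip(profile_before.calls, profile_after.calls):
        if b == a:
            calls.append(FLAT)
        elif a == ACTIVE:
            calls.append(UP)
        else:
            calls.append(DOWN)
    return calls


def generate_expression_table(profile_before: DiscreteProfile,
                              profile_after: DiscreteProfile,
                              node_map: dict[str, list[str]],
                              flip_rate: float = 0.1,
                              seed: int = 0,
                              node_names: list[str] | None = None) -> str:
    """Noisy observed-calls TSV consistent with a pair of attractor profiles.

    Each mapped gene carries its node's true differential call with
    probability 1 - flip_rate, else one of the two other calls uniformly.
    ``node_map`` is node -> gene symbols; ``node_names`` gives the profile's
    node order (defaults to node_map order).  Deterministic given ``seed``.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    truth = true_diff_calls(profile_before, profile_after)
    names = node_names if node_names is not None else list(node_map)
    truth_of = dict(zip(names, truth))
    rng = np.random.default_rng(seed)
    lines = ["gene\tcall"]
    for node in node_map:
        call = truth_of.get(node, FLAT)
        for gene in node_map[node]:
            emitted = call
            if rng.random() < flip_rate:
                emitted = CALLS[(CALLS.index(call) + int(rng.integers(1, 3))) % 3]
            lines.append(f"{gene}\t{emitted}")
    return "\n".join(lines) + "\n"
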