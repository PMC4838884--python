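"""Saddle-mediated transition graph among fixed points.

Attractors are the robust cell phenotypes; the saddle and other unstable
fixed points between them act as "passes" on the landscape.  Displacing an
unstable point slightly along each unstable eigendirection and following
the flow downhill identifies which attractors it drains into; collecting
those flows over all non-attractor fixed points yields a directed
transition graph whose derived attractor-adjacency (two attractors sharing
a saddle) summarizes which phenotype switches are dynamically accessible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dynamics import CompiledDynamics, ParameterSet, relax
from .fixed_points import ATTRACTOR, SADDLE, AttractorSet, FixedPoint
from .network import Network

EPS_DEFAULT = 1e-3


@dataclass
class FlowEdge:
    source: str          # id of the saddle/unstable point
    target: str          # id of the attractor reached
    direction: int       # which unstable direction (0-based)
    sign: int            # +1 / -1 displacement along that direction


@dataclass
class TransitionGraph:
    fixed_points: dict[str, FixedPoint]
    flow_edges: list[FlowEdge]
    novel_endpoints: list[np.ndarray] = field(default_factory=list)

    @property
    def attractor_ids(self) -> list[str]:
        return [k for k, fp in self.fixed_points.items()
                if fp.stability_class == ATTRACTOR]

    @property
    def adjacency(self) -> nx.Graph:
        """Attractor adjacency through shared saddles (index-1 points only)."""
        g = nx.Graph()
        g.add_nodes_from(self.attractor_ids)
        targets: dict[str, set[str]] = {}
        for fe in self.flow_edges:
            if self.fixed_points[fe.source].stability_class == SADDLE:
                targets.setdefault(fe.source, set()).add(fe.target)
        for sad, atts in targets.items():
            atts = sorted(atts)
            for i, a in enumerate(atts):
                for b in atts[i + 1:]:
                    if g.has_edge(a, b):
                        g[a][b]["saddles"].append(sad)
                    else:
                        g.add_edge(a, b, saddles=[sad])
        return g

    def to_json(self) -> str:
        doc = {
            "vertices": [
                {"id": k, "class": fp.stability_class, "index": fp.index,
                 "state": [round(float(v), 6) for v in fp.state]}
                for k, fp in self.fixed_points.items()],
            "flow_edges": [
                {"source": fe.source, "target": fe.target,
                 "direction": fe.direction, "sign": fe.sign}
                for fe in self.flow_edges],
            "adjacency": [{"a": a, "b": b, "saddles": d["saddles"]}
                          for a, b, d in self.adjacency.edges(data=True)],
        }
        return json.dumps(doc, indent=1)


def unstable_directions(dyn: CompiledDynamics, fp: FixedPoint) -> list[np.ndarray]:
    """Unit vectors spanning the unstable eigenspace.

    Complex unstable pairs contribute their (normalized) real and imaginary
    parts separately, spanning the unstable plane without integrating the
    linearization.
    """
    J = dyn.jacobian(fp.state)
    vals, vecs = np.linalg.eig(J)
    dirs: list[np.ndarray] = []
    seen_conj: set[int] = set()
    for k in np.argsort(-vals.real):
        if vals[k].real <= 0 or k in seen_conj:
            continue
        v = vecs[:, k]
        if abs(vals[k].imag) > 0:
            # pair with the conjugate; take real/imag parts once
            for kk in range(len(vals)):
                if kk != k and np.isclose(vals[kk], np.conj(vals[k])):
                    seen_conj.add(kk)
                    break
            for part in (v.real, v.imag):
                nrm = np.linalg.norm(part)
                if nrm > 1e-12:
                    dirs.append(part / nrm)
        else:
            part = v.real
            dirs.append(part / np.linalg.norm(part))
    return dirs


def escape_flows(net: Network, params: ParameterSet | None, fp: FixedPoint,
                 attractors: AttractorSet, eps: float = EPS_DEFAULT,
                 horizon: float = 100.0, tol: float = 1e-6,
                 dynamics: CompiledDynamics | None = None
                 ) -> tuple[set[int], list[tuple[int, int, int]], list[np.ndarray]]:
    """Attractors reached by perturbing off an unstable fixed point.

    Displaces ``fp`` by +/- ``eps`` along each unstable eigendirection and
    integrates to convergence.  Returns (set of attractor indices reached,
    flow records (direction, sign, attractor index), novel endpoints that
    matched no known attractor).
    """
    if fp.stability_class == ATTRACTOR:
        raise ValueError("escape_flows requires a saddle or unstable fixed point")
    if eps <= 0:
        raise ValueError("eps must be positive")
    dyn = dynamics or CompiledDynamics(net, params)
    reached: set[int] = set()
    flows: list[tuple[int, int, int]] = []
    novel: list[np.ndarray] = []
    for d, vec in enumerate(unstable_directions(dyn, fp)):
        for sign in (+1, -1):
            x0 = np.clip(fp.state + sign * eps * vec, 0.0, 1.0)
            x, converged = relax(net, params, x0, horizon=horizon, tol=tol,
                                 dynamics=dyn)
            if not converged:
                novel.append(x)
                continue
            m = attractors.match(x)
            if m is None:
                novel.append(x)
            else:
                reached.add(m)
                flows.append((d, sign, m))
    return reached, flows, novel


def build_transition_graph(net: Network, params: ParameterSet | None,
                           fps: list[FixedPoint], eps: float = EPS_DEFAULT,
                           horizon: float = 100.0, tol: float = 1e-6
                           ) -> TransitionGraph:
    """Apply :func:`escape_flows` to every non-attractor fixed point.

    Vertex ids: attractors A1, A2, ...; saddles S1, ...; other unstable
    points U1, ... in input order.
    """
    dyn = CompiledDynamics(net, params)
    atts = [fp for fp in fps if fp.stability_class == ATTRACTOR]
    if not atts:
        raise ValueError("transition graph needs at least one attractor")
    att_set = AttractorSet(points=atts, basin_counts=[0] * len(atts),
                           n_starts=0, seed=0)
    ids: dict[str, FixedPoint] = {}
    counters = {"A": 0, "S": 0, "U": 0}
    id_of: dict[int, str] = {}
    for fp in fps:
        prefix = {"attractor": "A", "saddle": "S"}.get(fp.stability_class, "U")
        counters[prefix] += 1
        fid = f"{prefix}{counters[prefix]}"
        ids[fid] = fp
        id_of[id(fp)] = fid
    att_ids = [id_of[id(fp)] for fp in atts]
    flow_edges: list[FlowEdge] = []
    novel_all: list[np.ndarray] = []
    for fp in fps:
        if fp.stability_class == ATTRACTOR:
            continue
        _, flows, novel = escape_flows(net, params, fp, att_set, eps=eps,
                                       horizon=horizon, tol=tol, dynamics=dyn)
        novel_all.extend(novel)
        for d, sign, m in flows:
            flow_edges.append(FlowEdge(source=id_of[id(fp)],
                                       target=att_ids[m],
                                       direction=d, sign=sign))
    return TransitionGraph(fixed_points=ids, flow_edges=flow_edges,
                           novel_endpoints=novel_all)


def find_route(graph: TransitionGraph, from_attractor: str, to_attractor: str,
               max_hops: int = 4) -> list[list[str]]:
    """Simple paths between attractors in the shared-saddle adjacency.

    Shortest routes first, lexicographic tie-break on the id sequence.
    """
    adj = graph.adjacency
    for a in (from_attractor, to_attractor):
        if a not in adj:
            raise KeyError(f"unknown attractor id {a!r}")
    if from_attractor == to_attractor:
        return [[from_attractor]]
    routes = [list(p) for p in nx.all_simple_paths(
        adj, from_attractor, to_attractor, cutoff=max_hops)]
    routes.sort(key=lambda p: (len(p), p))
    return routes
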