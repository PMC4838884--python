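"""Signed interaction networks with functional-module annotations.

A :class:`Network` is the static "wiring" of an endogenous molecular-cellular
network: named nodes grouped into functional modules (cell cycle, apoptosis,
...) and directed activation/inhibition edges, optionally carrying per-edge
Hill parameters.  Node order is stable and defines state-vector indexing
throughout the package.

Two plain-text dialects are supported:

* TSV: ``#module <label>`` header lines, then ``NODE <name> <module>`` and
  ``EDGE <source> <target> <+|-> [n a]`` lines.
* JSON: ``{"modules": [...], "nodes": [{name, module}], "edges": [...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

ACTIVATION = "activation"
INHIBITION = "inhibition"

_SIGN_CHARS = {"+": ACTIVATION, "-": INHIBITION}
_SIGN_TO_CHAR = {ACTIVATION: "+", INHIBITION: "-"}


class NetworkError(Exception):
    """Base class for network definition errors."""


class NetworkParseError(NetworkError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NetworkReferenceError(NetworkError):
    """An edge endpoint names an undeclared node."""


class DuplicateEdgeError(NetworkError):
    """More than one edge with the same (source, target, sign) triple."""


@dataclass(frozen=True)
class Node:
    name: str
    module: str = "default"
    description: str = ""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # ACTIVATION or INHIBITION
    n: float | None = None  # per-edge Hill coefficient (>= 1)
    a: float | None = None  # per-edge threshold in (0, 1)

    def __post_init__(self):
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"sign must be activation/inhibition, got {self.sign!r}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.sign)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_network`."""

    rule: str
    element: str
    message: str


@dataclass
class Network:
    nodes: list[Node]
    edges: list[Edge]
    modules: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.modules:
            self.modules = sorted({nd.module for nd in self.nodes})
        self._index = {nd.name: i for i, nd in enumerate(self.nodes)}

    # -- indexing helpers -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkReferenceError(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def in_edges(self, target: str) -> list[Edge]:
        return [e for e in self.edges if e.target == target]

    def regulators(self, target: str) -> tuple[list[Edge], list[Edge]]:
        """Activating and inhibiting in-edges of ``target``."""
        ins = self.in_edges(target)
        return ([e for e in ins if e.sign == ACTIVATION],
                [e for e in ins if e.sign == INHIBITION])


def validate_network(net: Network) -> list[Violation]:
    """Check all Network invariants; violations are returned, never raised."""
    out: list[Violation] = []
    seen_names: set[str] = set()
    for nd in net.nodes:
        if not nd.name:
            out.append(Violation("node-name", "<empty>", "node name is empty"))
        elif nd.name in seen_names:
            out.append(Violation("node-unique", nd.name, f"duplicate node name {nd.name!r}"))
        seen_names.add(nd.name)
        if nd.module not in net.modules:
            out.append(Violation(
                "module-label", nd.name,
                f"node {nd.name!r} has module {nd.module!r} not in declared modules"))
    seen_triples: set[tuple[str, str, str]] = set()
    for e in net.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in seen_names:
                out.append(Violation(
                    "edge-endpoint", f"{e.source}->{e.target}",
                    f"edge references undeclared node {endpoint!r}"))
        if e.triple in seen_triples:
            out.append(Violation(
                "edge-duplicate", f"{e.source}->{e.target}",
                f"duplicate edge ({e.source!r}, {e.target!r}, {e.sign})"))
        seen_triples.add(e.triple)
        if e.n is not None and not e.n >= 1:
            out.append(Violation("edge-param", f"{e.source}->{e.target}",
                                 f"Hill coefficient n={e.n} must be >= 1"))
        if e.a is not None and not (0 < e.a < 1):
            out.append(Violation("edge-param", f"{e.source}->{e.target}",
                                 f"threshold a={e.a} must lie in (0, 1)"))
    return out


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def parse_network(text: str, dialect: str | None = None) -> Network:
    """Parse a network definition document (TSV or JSON dialect).

    ``dialect`` is auto-detected from the first non-blank character when
    not given.  Node order in the document defines state-vector indexing.
    """
    if dialect is None:
        stripped = text.lstrip()
        dialect = "json" if stripped.startswith("{") else "tsv"
    if dialect == "json":
        net = _parse_json(text)
    elif dialect == "tsv":
        net = _parse_tsv(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _raise_on_structural(net)
    return net


def _raise_on_structural(net: Network) -> None:
    names = {nd.name for nd in net.nodes}
    seen: set[tuple[str, str, str]] = set()
    for e in net.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in names:
                raise NetworkReferenceError(
                    f"edge {e.source!r} -> {e.target!r} references undeclared "
                    f"node {endpoint!r}")
        if e.triple in seen:
            raise DuplicateEdgeError(
                f"duplicate edge ({e.source!r}, {e.target!r}, {e.sign})")
        seen.add(e.triple)


def _parse_tsv(text: str) -> Network:
    modules: list[str] = []
    nodes: list[Node] = []
    edges: list[Edge] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or (line.startswith("#") and not line.startswith("#module")):
            continue
        fields = line.split()
        kind = fields[0]
        if kind == "#module":
            if len(fields) < 2:
                raise NetworkParseError("#module line missing label", lineno)
            label = " ".join(fields[1:])
            if label not in modules:
                modules.append(label)
        elif kind == "NODE":
            if len(fields) < 2:
                raise NetworkParseError("NODE line needs a name", lineno)
            name = fields[1]
            module = fields[2] if len(fields) > 2 else (modules[0] if modules else "default")
            nodes.append(Node(name=name, module=module))
        elif kind == "EDGE":
            if len(fields) < 4:
                raise NetworkParseError("EDGE line needs source, target, sign", lineno)
            src, tgt, sign_char = fields[1], fields[2], fields[3]
            if sign_char not in _SIGN_CHARS:
                raise NetworkParseError(f"edge sign must be + or -, got {sign_char!r}", lineno)
            n = a = None
            if len(fields) >= 6:
                try:
                    n, a = float(fields[4]), float(fields[5])
                except ValueError:
                    raise NetworkParseError("edge parameters must be numeric", lineno) from None
            elif len(fields) == 5:
                raise NetworkParseError("edge parameters require both n and a", lineno)
            edges.append(Edge(src, tgt, _SIGN_CHARS[sign_char], n=n, a=a))
        else:
            raise NetworkParseError(f"unrecognized record {kind!r}", lineno)
    if not modules:
        modules = sorted({nd.module for nd in nodes}) or ["default"]
    return Network(nodes=nodes, edges=edges, modules=modules)


def _parse_json(text: str) -> Network:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkParseError(str(exc), exc.lineno) from None
    nodes = [Node(name=d["name"], module=d.get("module", "default"),
                  description=d.get("description", ""))
             for d in doc.get("nodes", [])]
    edges = []
    for d in doc.get("edges", []):
        sign = d["sign"]
        if sign in _SIGN_CHARS:
            sign = _SIGN_CHARS[sign]
        edges.append(Edge(d["source"], d["target"], sign,
                          n=d.get("n"), a=d.get("a")))
    modules = list(doc.get("modules", [])) or sorted({nd.module for nd in nodes})
    return Network(nodes=nodes, edges=edges, modules=modules)


def write_network(net: Network, dialect: str = "tsv") -> str:
    """Serialize a network; round-trips through :func:`parse_network`."""
    if not net.nodes:
        raise NetworkError("cannot write a network with no nodes")
    violations = validate_network(net)
    if violations:
        raise NetworkError(
            "invalid network: " + "; ".join(v.message for v in violations))
    if dialect == "tsv":
        lines = [f"#module {m}" for m in net.modules]
        lines += [f"NODE\t{nd.name}\t{nd.module}" for nd in net.nodes]
        for e in net.edges:
            rec = f"EDGE\t{e.source}\t{e.target}\t{_SIGN_TO_CHAR[e.sign]}"
            if e.n is not None and e.a is not None:
                rec += f"\t{e.n!r}\t{e.a!r}"
            lines.append(rec)
        return "\n".join(lines) + "\n"
    if dialect == "json":
        doc = {
            "modules": net.modules,
            "nodes": [{"name": nd.name, "module": nd.module} for nd in net.nodes],
            "edges": [
                {k: v for k, v in
                 {"source": e.source, "target": e.target, "sign": e.sign,
                  "n": e.n, "a": e.a}.items() if v is not None}
                for e in net.edges],
        }
        return json.dumps(doc, indent=1) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# state-dependent views
# ---------------------------------------------------------------------------

def effective_subnetwork(net: Network, state, threshold: float = 0.5) -> Network:
    """Induced subnetwork on active nodes (value strictly above ``threshold``).

    Only edges with both endpoints retained survive.  This is the
    attractor-specific "effective wiring" view: the sub-network a cell in
    that state is actually running.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_nodes,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({net.n_nodes},)")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    keep = {nd.name for nd, v in zip(net.nodes, state) if v > threshold}
    nodes = [nd for nd in net.nodes if nd.name in keep]
    edges = [e for e in net.edges if e.source in keep and e.target in keep]
    modules = [m for m in net.modules if any(nd.module == m for nd in nodes)]
    return Network(nodes=nodes, edges=edges, modules=modules or ["default"])


def subnetwork_equal(a: Network, b: Network) -> bool:
    """Structural equality up to field ordering (used in round-trip tests)."""
    return ([replace(n, description="") for n in a.nodes]
            == [replace(n, description="") for n in b.nodes]
            and sorted(a.edges, key=lambda e: e.triple)
            == sorted(b.edges, key=lambda e: e.triple))
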