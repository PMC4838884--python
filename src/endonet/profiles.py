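"""Discrete activity profiles and concordance with expression call tables.

Attractor states are near-binary; thresholding at 0.5 turns each into an
on/off molecular profile (the phenotype signature).  Comparing two states
node-by-node gives an up/down/flat differential profile, which can be
scored against externally observed up/down calls (e.g. discretized
microarray contrasts) through a node-to-gene name map.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixed_points import AttractorSet
from .network import Network

ACTIVE, INACTIVE = "active", "inactive"
UP, DOWN, FLAT = "up", "down", "flat"
DEFAULT_DELTA = 0.2


@dataclass(frozen=True)
class DiscreteProfile:
    calls: tuple[str, ...]          # per node: active / inactive
    threshold: float

    def __iter__(self):
        return iter(self.calls)


@dataclass(frozen=True)
class DiffProfile:
    calls: tuple[str, ...]          # per node: up / down / flat
    delta: float


@dataclass
class ConcordanceScore:
    agree: int
    compared: int
    score: float
    per_node: dict[str, tuple[str, str]]   # node -> (model call, observed call)


def discretize(state, threshold: float = 0.5) -> DiscreteProfile:
    """Strictly-above-threshold activity calls."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    state = np.asarray(state, dtype=float)
    return DiscreteProfile(
        calls=tuple(ACTIVE if v > threshold else INACTIVE for v in state),
        threshold=threshold)


def profile_table(attractors: AttractorSet, net: Network,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Attractor-by-node table of activity calls (rows in id order)."""
    if not attractors.points:
        raise ValueError("attractor set is empty")
    rows = {aid: list(discretize(fp.state, threshold).calls)
            for aid, fp in zip(attractors.ids, attractors.points)}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=net.node_names)


def diff_call(before, after, delta: float = DEFAULT_DELTA) -> DiffProfile:
    """Per-node up/down/flat calls for an ordered (before -> after) pair."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("state dimensions differ")
    calls = []
    for b, a in zip(before, after):
        if a - b > delta:
            calls.append(UP)
        elif b - a > delta:
            calls.append(DOWN)
        else:
            calls.append(FLAT)
    return DiffProfile(calls=tuple(calls), delta=delta)


def read_calls_table(text: str) -> dict[str, str]:
    """Parse an observed-calls TSV (columns: gene, call in {up,down,flat})."""
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                     names=["gene", "call"], header=None, dtype=str)
    if len(df) and df.iloc[0].tolist() == ["gene", "call"]:
        df = df.iloc[1:]
    out = {}
    for gene, call in zip(df["gene"], df["call"]):
        call = call.strip().lower()
        if call not in (UP, DOWN, FLAT):
            raise ValueError(f"bad call {call!r} for gene {gene!r}")
        out[gene.strip()] = call
    return out


def _observed_node_calls(net: Network, observed: dict[str, str],
                         node_map: dict[str, list[str]] | None
                         ) -> tuple[dict[str, str], int]:
    """Map gene-level calls to node-level calls; majority vote, ties flat."""
    if node_map is None:
        node_map = {name: [name] for name in net.node_names}
    node_calls: dict[str, str] = {}
    n_unmapped = len(set(observed) - {g for gs in node_map.values() for g in gs})
    for node, genes in node_map.items():
        votes = Counter(observed[g] for g in genes if g in observed)
        if not votes:
            continue
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            node_calls[node] = FLAT
        else:
            node_calls[node] = top[0][0]
    return node_calls, n_unmapped


def concordance(model: DiffProfile, observed, net: Network,
                node_map: dict[str, list[str]] | None = None
                ) -> ConcordanceScore:
    """Agreement between a model differential profile and observed calls.

    ``observed`` is either a DiffProfile over the same network or a
    gene->call mapping resolved through ``node_map`` (node -> gene symbols;
    multi-gene nodes aggregate by majority, ties flat).  The score counts
    only nodes called non-flat on both sides.
    """
    if isinstance(observed, DiffProfile):
        obs_calls = dict(zip(net.node_names, observed.calls))
    else:
        obs_calls, _ = _observed_node_calls(net, observed, node_map)
    per_node: dict[str, tuple[str, str]] = {}
    agree = compared = 0
    for name, m_call in zip(net.node_names, model.calls):
        o_call = obs_calls.get(name)
        if o_call is None:
            continue
        per_node[name] = (m_call, o_call)
        if m_call != FLAT and o_call != FLAT:
            compared += 1
            if m_call == o_call:
                agree += 1
    if compared == 0:
        raise ValueError("no nodes are non-flat in both profiles")
    return ConcordanceScore(agree=agree, compared=compared,
                            score=agree / compared, per_node=per_node)
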