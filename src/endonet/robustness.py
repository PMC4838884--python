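"""Attractor persistence under random per-edge parameter resampling.

Real interactions do not share one Hill coefficient and threshold; the
census is only meaningful if the attractors it reports survive when every
edge gets its own randomly drawn (n_i, a_i).  Each resample redraws the
parameters, reruns the attractor search, and asks whether each reference
attractor recurs — matched primarily by its discretized (>0.5) activity
profile, since parameter changes shift attractor coordinates continuously
but leave the on/off pattern intact, with a max-norm distance fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dynamics import ParameterSet
from .fixed_points import AttractorSet, sample_attractors
from .network import Network

DEFAULT_N_RANGE = (2.0, 5.0)
DEFAULT_A_RANGE = (0.3, 0.7)


@dataclass
class RobustnessReport:
    n_resamples: int
    seed: int
    recurrence: dict[str, float]      # reference attractor id -> fraction
    match_tol: float
    parameter_ranges: dict[str, tuple[float, float]]
    starts_per_resample: int
    matched_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "recurrence": self.recurrence,
            "matched_counts": self.matched_counts,
            "match_tol": self.match_tol,
            "parameter_ranges": {k: list(v)
                                 for k, v in self.parameter_ranges.items()},
            "starts_per_resample": self.starts_per_resample,
        }, indent=1)


def resample_parameters(net: Network,
                        n_range: tuple[float, float] = DEFAULT_N_RANGE,
                        a_range: tuple[float, float] = DEFAULT_A_RANGE,
                        mode: str = "independent",
                        seed: int = 0) -> ParameterSet:
    """Per-edge uniform draws of (n_i, a_i); deterministic given ``seed``.

    ``independent`` draws n and a separately per edge; ``coupled`` draws a
    single fraction per edge and places both n and a at that fraction of
    their intervals (the dependent variant of the random test).
    """
    lo_n, hi_n = n_range
    lo_a, hi_a = a_range
    if not (1 <= lo_n <= hi_n):
        raise ValueError("n interval must satisfy 1 <= lo <= hi")
    if not (0 < lo_a <= hi_a < 1):
        raise ValueError("a interval must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    m = len(net.edges)
    if mode == "independent":
        n = rng.uniform(lo_n, hi_n, size=m)
        a = rng.uniform(lo_a, hi_a, size=m)
    elif mode == "coupled":
        u = rng.uniform(0.0, 1.0, size=m)
        n = lo_n + u * (hi_n - lo_n)
        a = lo_a + u * (hi_a - lo_a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ParameterSet.per_edge(n, a)


def _matches(reference, found: AttractorSet, match_tol: float) -> bool:
    ref_profile = reference.profile()
    for fp in found.points:
        if fp.profile() == ref_profile:
            return True
    return found.match(reference.state, tol=match_tol) is not None


def recurrence_statistics(net: Network, reference: AttractorSet,
                          n_range: tuple[float, float] = DEFAULT_N_RANGE,
                          a_range: tuple[float, float] = DEFAULT_A_RANGE,
                          n_resamples: int = 50, seed: int = 0,
                          starts_per_resample: int = 200,
                          match_tol: float = 0.1,
                          mode: str = "independent") -> RobustnessReport:
    """Recurrence rate of each reference attractor over parameter resamples.

    For each resample: draw per-edge parameters, rerun the attractor
    search (``starts_per_resample`` random starts), and mark each reference
    attractor matched if some found attractor shares its discretized
    profile (primary) or lies within ``match_tol`` in max norm (secondary).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not reference.points:
        raise ValueError("reference attractor set is empty")
    counts = {rid: 0 for rid in reference.ids}
    for k in range(n_resamples):
        params = resample_parameters(net, n_range, a_range, mode=mode,
                                     seed=seed + 1000 * (k + 1))
        found = sample_attractors(net, params, n_starts=starts_per_resample,
                                  seed=seed + k)
        for rid, ref in zip(reference.ids, reference.points):
            if _matches(ref, found, match_tol):
                counts[rid] += 1
    recurrence = {rid: c / n_resamples for rid, c in counts.items()}
    return RobustnessReport(
        n_resamples=n_resamples, seed=seed, recurrence=recurrence,
        match_tol=match_tol,
        parameter_ranges={"n": tuple(n_range), "a": tuple(a_range)},
        starts_per_resample=starts_per_resample, matched_counts=counts)
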