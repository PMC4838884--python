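"""Fixed-point enumeration and stability classification.

Two complementary search strategies mirror how multistable gene-network
models are censused in practice: (i) forward integration from many random
initial states finds the attractors (stable fixed points with non-trivial
basins) together with basin tallies, and (ii) damped-Newton root finding
from random interior seeds and from midpoints between attractor pairs picks
up the saddle and other unstable fixed points that forward flow can never
reach.  Stability is read off the Jacobian spectrum:

    index = #{eigenvalues with positive real part}
    0 -> attractor, 1 -> saddle, >=2 -> unstable;

eigenvalues with |Re| below a degeneracy tolerance flag the point as
degenerate rather than silently classifying it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import CompiledDynamics, ParameterSet, relax
from .network import Network

DEDUP_TOL = 1e-3
CONVERGE_TOL = 1e-6
RELAX_HORIZON = 100.0
DEGENERACY_TOL = 1e-6

ATTRACTOR = "attractor"
SADDLE = "saddle"
UNSTABLE = "unstable"
DEGENERATE = "degenerate"


class RefinementError(Exception):
    """Newton refinement failed; carries the best iterate found."""

    def __init__(self, message: str, best_iterate=None, residual=None):
        super().__init__(message)
        self.best_iterate = best_iterate
        self.residual = residual


@dataclass
class FixedPoint:
    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stability_class: str
    index: int

    def profile(self, threshold: float = 0.5) -> tuple[int, ...]:
        """Discretized activity pattern (strict > threshold)."""
        return tuple(int(v > threshold) for v in self.state)


@dataclass
class AttractorSet:
    points: list[FixedPoint]
    basin_counts: list[int]
    n_starts: int
    seed: int
    n_nonconverged: int = 0
    dedup_tol: float = DEDUP_TOL
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"A{i + 1}" for i in range(len(self.points))]

    def __len__(self):
        return len(self.points)

    def match(self, state, tol: float | None = None) -> int | None:
        """Index of the attractor within max-norm ``tol`` of ``state``."""
        tol = self.dedup_tol if tol is None else tol
        state = np.asarray(state, dtype=float)
        for i, fp in enumerate(self.points):
            if np.max(np.abs(fp.state - state)) < tol:
                return i
        return None

    def by_id(self, att_id: str) -> FixedPoint:
        return self.points[self.ids.index(att_id)]


def classify_fixed_point(eigenvalues, degeneracy_tol: float = DEGENERACY_TOL
                         ) -> tuple[str, int]:
    """Stability class and index from the Jacobian spectrum."""
    re = np.real(np.asarray(eigenvalues))
    if np.any(np.abs(re) < degeneracy_tol):
        return DEGENERATE, int(np.sum(re > 0))
    index = int(np.sum(re > 0))
    if index == 0:
        return ATTRACTOR, 0
    if index == 1:
        return SADDLE, 1
    return UNSTABLE, index


def dedupe(states, tol: float = DEDUP_TOL) -> tuple[list[np.ndarray], list[int]]:
    """Greedy max-norm clustering in input order.

    Each state joins the first representative within ``tol``, else opens a
    new cluster; returns (representatives, membership per input state).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    reps: list[np.ndarray] = []
    members: list[int] = []
    for s in states:
        s = np.asarray(s, dtype=float)
        for i, r in enumerate(reps):
            if np.max(np.abs(r - s)) < tol:
                members.append(i)
                break
        else:
            reps.append(s)
            members.append(len(reps) - 1)
    return reps, members


def _make_fixed_point(dyn: CompiledDynamics, state: np.ndarray,
                      degeneracy_tol: float = DEGENERACY_TOL) -> FixedPoint:
    state = np.asarray(state, dtype=float)
    residual = float(np.max(np.abs(dyn.rhs(state))))
    eig = np.linalg.eigvals(dyn.jacobian(state))
    cls, index = classify_fixed_point(eig, degeneracy_tol)
    return FixedPoint(state=state, residual=residual, eigenvalues=eig,
                      stability_class=cls, index=index)


def refine_fixed_point(net: Network, params: ParameterSet | None, guess,
                       tol: float = 1e-10, max_iter: int = 100,
                       dynamics: CompiledDynamics | None = None) -> FixedPoint:
    """Damped Newton solve of rhs(x)=0 with iterates projected into [0,1]^N.

    Backtracking halves the step until the residual norm decreases; failure
    to converge within ``max_iter`` raises :class:`RefinementError` carrying
    the best iterate.
    """
    dyn = dynamics or CompiledDynamics(net, params)
    x = np.clip(np.asarray(guess, dtype=float).copy(), 0.0, 1.0)
    best_x, best_r = x.copy(), float(np.max(np.abs(dyn.rhs(x))))
    for _ in range(max_iter):
        r = dyn.rhs(x)
        rn = float(np.max(np.abs(r)))
        if rn < best_r:
            best_x, best_r = x.copy(), rn
        if rn < tol:
            return _make_fixed_point(dyn, x)
        J = dyn.jacobian(x)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        lam = 1.0
        improved = False
        for _ in range(30):
            x_new = np.clip(x + lam * step, 0.0, 1.0)
            if float(np.max(np.abs(dyn.rhs(x_new)))) < rn:
                x = x_new
                improved = True
                break
            lam *= 0.5
        if not improved:
            raise RefinementError("Newton refinement stalled",
                                  best_iterate=best_x, residual=best_r)
    raise RefinementError(f"no convergence in {max_iter} iterations",
                          best_iterate=best_x, residual=best_r)


def sample_attractors(net: Network, params: ParameterSet | None = None,
                      n_starts: int = 10_000, seed: int = 0,
                      horizon: float = RELAX_HORIZON, tol: float = CONVERGE_TOL,
                      dedup_tol: float = DEDUP_TOL) -> AttractorSet:
    """Attractor census from random initial conditions.

    Integrates from ``n_starts`` uniform random states; a start counts as
    converged when the max-norm of the rhs drops below ``tol``.  Endpoints
    are Newton-refined, deduplicated (greedy, max-norm ``dedup_tol``) and
    classified; basin tallies record how many starts reached each attractor.
    Bit-for-bit reproducible from ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    dyn = CompiledDynamics(net, params)
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 1.0, size=(n_starts, net.n_nodes))
    endpoints: list[np.ndarray] = []
    n_bad = 0
    for x0 in starts:
        x, converged = relax(net, params, x0, horizon=horizon, tol=tol,
                             dynamics=dyn)
        if not converged:
            n_bad += 1
            continue
        try:
            fp = refine_fixed_point(net, params, x, dynamics=dyn)
            endpoints.append(fp.state)
        except RefinementError:
            endpoints.append(x)
    reps, members = dedupe(endpoints, tol=dedup_tol)
    points, counts = [], []
    for i, r in enumerate(reps):
        fp = _make_fixed_point(dyn, r)
        if fp.stability_class != ATTRACTOR:
            # a start can stall on a slow manifold near a saddle; keep only
            # genuinely stable endpoints in the attractor census
            n_bad += members.count(i)
            continue
        points.append(fp)
        counts.append(members.count(i))
    return AttractorSet(points=points, basin_counts=counts, n_starts=n_starts,
                        seed=seed, n_nonconverged=n_bad, dedup_tol=dedup_tol)


def enumerate_fixed_points(net: Network, params: ParameterSet | None = None,
                           n_seeds: int = 200, seed: int = 0,
                           n_starts: int = 500,
                           dedup_tol: float = DEDUP_TOL,
                           attractors: AttractorSet | None = None
                           ) -> list[FixedPoint]:
    """All-class fixed-point census.

    Union of (i) the attractors from :func:`sample_attractors`, (ii) Newton
    refinements from ``n_seeds`` random interior seeds, and (iii) Newton
    refinements from midpoints of segments joining attractor pairs (saddles
    sit on basin boundaries between adjacent attractors).  Deduplicated and
    classified; deterministic given ``seed``.
    """
    dyn = CompiledDynamics(net, params)
    if attractors is None:
        attractors = sample_attractors(net, params, n_starts=n_starts,
                                       seed=seed, dedup_tol=dedup_tol)
    candidates: list[np.ndarray] = [fp.state for fp in attractors.points]
    rng = np.random.default_rng(seed + 1)
    seeds = rng.uniform(0.05, 0.95, size=(n_seeds, net.n_nodes))
    mids = [(a.state + b.state) / 2.0
            for i, a in enumerate(attractors.points)
            for b in attractors.points[i + 1:]]
    for guess in list(seeds) + mids:
        try:
            fp = refine_fixed_point(net, params, guess, dynamics=dyn)
        except RefinementError:
            continue
        candidates.append(fp.state)
    reps, _ = dedupe(candidates, tol=dedup_tol)
    return [_make_fixed_point(dyn, r) for r in reps]


def census(fps: list[FixedPoint]) -> dict[str, int]:
    """Count fixed points by stability class."""
    out = {ATTRACTOR: 0, SADDLE: 0, UNSTABLE: 0, DEGENERATE: 0}
    for fp in fps:
        out[fp.stability_class] += 1
    return out
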