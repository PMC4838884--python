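"""Continuous Hill-type ODE dynamics and Boolean dynamics for signed networks.

The continuous model is the normalized coarse-grained rate equation

    dx_i/dt = f_i(x) - x_i ,        x_i in [0, 1],

where every agent self-degrades exponentially on a unit timescale and the
generation rate ``f_i`` is a saturating Hill composition of the node's
regulators: activating inputs are summed inside one Hill function,

    A_i = S_A / (1 + S_A),          S_A = sum_j (x_j / a_j)^{n_j},

and inhibiting inputs form a single repressive factor,

    I_i = 1 / (1 + S_I),            S_I = sum_k (x_k / a_k)^{n_k},

with ``f_i = A_i * I_i``.  With a single regulator and global parameters
this reduces to the textbook forms x^n/(a^n + x^n) (activation, half
activity at x=a) and a^n/(a^n + x^n) (inhibition), which are complementary.
A node with inhibitors only has f_i = I_i (full generation when
uninhibited); a node with no regulators has f_i = 0 and decays.

Since 0 <= f_i <= 1 and degradation is -x_i, the unit box [0,1]^N is
forward-invariant: trajectories started inside never leave.

The Boolean counterpart discretizes the same logic: a node switches on iff
its activation condition holds (at least one activator on; vacuous for
nodes without activators) and no inhibitor is on; input-free nodes decay
to 0.  Alternate continuous rate laws can be swapped in through the
:class:`RateLaw` interface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import ACTIVATION, Network

DEFAULT_N = 3.0
DEFAULT_A = 0.5


class DynamicsError(Exception):
    pass


class IntegrationError(DynamicsError):
    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """Hill parameters, either one global (n, a) pair or per-edge vectors.

    ``n`` is the Hill coefficient (steepness, dimensionless, >= 1) and
    ``a`` the activity threshold on the normalized [0,1] scale.  Per-edge
    vectors align with the owning network's edge order.  Per-edge values
    stored on :class:`~endonet.network.Edge` override either mode.
    """

    mode: str = "global"  # "global" | "per_edge"
    n: float | np.ndarray = DEFAULT_N
    a: float | np.ndarray = DEFAULT_A

    def __post_init__(self):
        if self.mode not in ("global", "per_edge"):
            raise ValueError(f"unknown mode {self.mode!r}")
        n = np.asarray(self.n, dtype=float)
        a = np.asarray(self.a, dtype=float)
        if np.any(n < 1):
            raise ValueError("all Hill coefficients must be >= 1")
        if np.any((a <= 0) | (a >= 1)):
            raise ValueError("all thresholds must lie in (0, 1)")

    @classmethod
    def global_params(cls, n: float = DEFAULT_N, a: float = DEFAULT_A) -> "ParameterSet":
        return cls(mode="global", n=float(n), a=float(a))

    @classmethod
    def per_edge(cls, n, a) -> "ParameterSet":
        n = np.asarray(n, dtype=float)
        a = np.asarray(a, dtype=float)
        if n.shape != a.shape:
            raise ValueError("per-edge n and a must have the same length")
        return cls(mode="per_edge", n=n, a=a)

    def edge_params(self, net: Network) -> tuple[np.ndarray, np.ndarray]:
        """(n, a) arrays aligned with ``net.edges``; edge overrides applied."""
        m = len(net.edges)
        if self.mode == "global":
            n = np.full(m, float(self.n))
            a = np.full(m, float(self.a))
        else:
            n = np.asarray(self.n, dtype=float).copy()
            a = np.asarray(self.a, dtype=float).copy()
            if n.shape != (m,):
                raise ValueError(
                    f"per-edge vectors have length {n.shape}, network has {m} edges")
        for i, e in enumerate(net.edges):
            if e.n is not None:
                n[i] = e.n
            if e.a is not None:
                a[i] = e.a
        return n, a


# ---------------------------------------------------------------------------
# rate law
# ---------------------------------------------------------------------------

def activation_term(x: float, n: float = DEFAULT_N, a: float = DEFAULT_A) -> float:
    """Saturating Hill activation x^n / (a^n + x^n); 0.5 at x = a."""
    _check_rate_args(x, n, a)
    x = np.asarray(x, dtype=float)
    return x ** n / (a ** n + x ** n)


def inhibition_term(x: float, n: float = DEFAULT_N, a: float = DEFAULT_A) -> float:
    """Repressive Hill term a^n / (a^n + x^n); complementary to activation."""
    _check_rate_args(x, n, a)
    x = np.asarray(x, dtype=float)
    return a ** n / (a ** n + x ** n)


def _check_rate_args(x, n, a):
    if np.any((np.asarray(x) < 0) | (np.asarray(x) > 1)):
        raise ValueError("input activity must lie in [0, 1]")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    if not 0 < a < 1:
        raise ValueError("threshold must lie in (0, 1)")


class RateLaw:
    """Pluggable generation-rate law.

    Maps the per-node summed scaled inputs S_A (activators) and S_I
    (inhibitors) to a generation rate in [0, 1], vectorized over nodes.
    ``has_act`` / ``has_inh`` mark which nodes possess regulators of each
    sign.  The shipped default is the additive-within-one-Hill composition
    described in the module docstring; alternative forms used for
    sensitivity checks can subclass.
    """

    def rate(self, s_act, s_inh, has_act, has_inh):
        raise NotImplementedError

    def d_rate(self, s_act, s_inh, has_act, has_inh):
        """Partial derivatives (d/dS_A, d/dS_I) of the rate, per node."""
        raise NotImplementedError


class HillRateLaw(RateLaw):
    def _factors(self, s_act, s_inh, has_act, has_inh):
        act = np.where(has_act, s_act / (1.0 + s_act), 1.0)
        inh = np.where(has_inh, 1.0 / (1.0 + s_inh), 1.0)
        return act, inh

    def rate(self, s_act, s_inh, has_act, has_inh):
        act, inh = self._factors(s_act, s_inh, has_act, has_inh)
        return np.where(has_act | has_inh, act * inh, 0.0)

    def d_rate(self, s_act, s_inh, has_act, has_inh):
        act, inh = self._factors(s_act, s_inh, has_act, has_inh)
        d_act = np.where(has_act, inh / (1.0 + s_act) ** 2, 0.0)
        d_inh = np.where(has_inh, -act / (1.0 + s_inh) ** 2, 0.0)
        return d_act, d_inh


HILL = HillRateLaw()


class CompiledDynamics:
    """Network + parameters compiled to fast rhs / Jacobian callables.

    Precomputes edge-index arrays (source, target, n, a per sign) so that
    rhs and Jacobian evaluation are a handful of vectorized numpy ops.
    """

    def __init__(self, net: Network, params: ParameterSet | None = None,
                 rate_law: RateLaw = HILL):
        self.net = net
        self.params = params or ParameterSet.global_params()
        self.rate_law = rate_law
        n_e, a_e = self.params.edge_params(net)
        N = self.n_nodes = net.n_nodes
        groups = {}
        for want_act in (True, False):
            ks = [k for k, e in enumerate(net.edges)
                  if (e.sign == ACTIVATION) == want_act]
            groups[want_act] = (
                np.array([net.index(net.edges[k].source) for k in ks], int),
                np.array([net.index(net.edges[k].target) for k in ks], int),
                n_e[ks] if ks else np.empty(0),
                a_e[ks] if ks else np.empty(0),
            )
        self._act_edges = groups[True]
        self._inh_edges = groups[False]
        self._has_act = np.zeros(N, dtype=bool)
        self._has_inh = np.zeros(N, dtype=bool)
        self._has_act[self._act_edges[1]] = True
        self._has_inh[self._inh_edges[1]] = True

    def _check(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_nodes,):
            raise ValueError(
                f"state has shape {x.shape}, expected ({self.n_nodes},)")
        return x

    def _sums(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = []
        for src, tgt, n, a in (self._act_edges, self._inh_edges):
            s = np.zeros(self.n_nodes)
            if src.size:
                np.add.at(s, tgt, (x[src] / a) ** n)
            out.append(s)
        return out[0], out[1]

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Generation-rate vector f(x)."""
        x = self._check(x)
        s_a, s_i = self._sums(x)
        return self.rate_law.rate(s_a, s_i, self._has_act, self._has_inh)

    def node_rate(self, x: np.ndarray, i: int) -> float:
        return float(self.rates(x)[i])

    def rhs(self, x: np.ndarray) -> np.ndarray:
        x = self._check(x)
        return self.rates(x) - x

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        x = self._check(x)
        s_a, s_i = self._sums(x)
        dA, dI = self.rate_law.d_rate(s_a, s_i, self._has_act, self._has_inh)
        J = np.zeros((self.n_nodes, self.n_nodes))
        for (src, tgt, n, a), dF in ((self._act_edges, dA),
                                     (self._inh_edges, dI)):
            if not src.size:
                continue
            xs = x[src]
            # dS/dx_src; the x->0 limit is 0 for n>1 and 1/a for n=1
            with np.errstate(divide="ignore", invalid="ignore"):
                dS = n * xs ** (n - 1.0) / a ** n
            dS = np.where((xs == 0.0) & (n == 1.0), n / a, dS)
            dS = np.where((xs == 0.0) & (n > 1.0), 0.0, dS)
            np.add.at(J, (tgt, src), dF[tgt] * dS)
        J -= np.eye(self.n_nodes)
        return J


# functional facade -----------------------------------------------------------

def node_rate(net: Network, params: ParameterSet, node: str, state) -> float:
    """Generation rate f_i of one node; depends only on its in-neighbors."""
    i = net.index(node)
    return CompiledDynamics(net, params).node_rate(np.asarray(state, float), i)


def rhs(net: Network, params: ParameterSet, state) -> np.ndarray:
    return CompiledDynamics(net, params).rhs(np.asarray(state, float))


def jacobian(net: Network, params: ParameterSet, state) -> np.ndarray:
    return CompiledDynamics(net, params).jacobian(np.asarray(state, float))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time course of the network state (times in degradation-time units)."""

    times: np.ndarray
    states: np.ndarray  # shape (T, N)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self, net: Network):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=net.node_names)
        df.insert(0, "time", self.times)
        return df


def _clamp_arrays(net: Network, clamps: dict[str, float] | None):
    idx, vals = [], []
    for name, v in (clamps or {}).items():
        if name not in net:
            raise DynamicsError(f"clamp target {name!r} is not a network node")
        if not 0 <= v <= 1:
            raise DynamicsError(f"clamp value {v} for {name!r} outside [0, 1]")
        idx.append(net.index(name))
        vals.append(float(v))
    return np.array(idx, dtype=int), np.array(vals)


def integrate(net: Network, params: ParameterSet | None, x0, horizon: float,
              clamps: dict[str, float] | None = None,
              rtol: float = 1e-8, atol: float = 1e-10,
              converge_tol: float | None = None,
              dynamics: CompiledDynamics | None = None) -> Trajectory:
    """Integrate the ODE from ``x0`` for ``horizon`` time units.

    Clamped nodes are held exactly at their clamp value (zero derivative);
    with ``converge_tol`` set, integration stops early once the max-norm of
    the free-coordinate derivative drops below it.  Uses an adaptive
    stiff-capable solver (LSODA) with an analytic Jacobian: Hill
    nonlinearities get steep at large n.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    dyn = dynamics or CompiledDynamics(net, params)
    x0 = np.asarray(x0, dtype=float).copy()
    if x0.shape != (dyn.n_nodes,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({dyn.n_nodes},)")
    if np.any((x0 < 0) | (x0 > 1)):
        raise ValueError("x0 must lie in [0, 1]^N")
    cidx, cvals = _clamp_arrays(net, clamps)
    x0[cidx] = cvals
    free = np.ones(dyn.n_nodes, dtype=bool)
    free[cidx] = False

    def fun(t, x):
        d = dyn.rhs(np.clip(x, 0.0, 1.0))
        d[~free] = 0.0
        return d

    def jac(t, x):
        J = dyn.jacobian(np.clip(x, 0.0, 1.0))
        J[~free, :] = 0.0
        return J

    events = None
    if converge_tol is not None:
        # stop at half the tolerance so the endpoint satisfies a strict
        # residual < converge_tol check despite event-location error
        def settled(t, x):
            return float(np.max(np.abs(fun(t, x)))) - 0.5 * converge_tol
        settled.terminal = True
        settled.direction = -1
        events = [settled]

    sol = solve_ivp(fun, (0.0, horizon), x0, method="LSODA", jac=jac,
                    rtol=rtol, atol=atol, events=events, dense_output=False)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}",
                               last_state=sol.y[:, -1] if sol.y.size else x0)
    times = sol.t
    states = sol.y.T
    states[:, cidx] = cvals  # clamps are exact by construction
    return Trajectory(times=times, states=states)


def relax(net: Network, params: ParameterSet | None, x0,
          horizon: float = 100.0, tol: float = 1e-6,
          dynamics: CompiledDynamics | None = None) -> tuple[np.ndarray, bool]:
    """Integrate toward steady state; return (endpoint, converged?)."""
    dyn = dynamics or CompiledDynamics(net, params)
    traj = integrate(net, params, x0, horizon, converge_tol=tol, dynamics=dyn)
    x = np.clip(traj.final_state, 0.0, 1.0)
    return x, bool(np.max(np.abs(dyn.rhs(x))) < tol)


# ---------------------------------------------------------------------------
# Boolean dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanAttractor:
    """A fixed point (period 1) or cycle of the synchronous Boolean map."""

    states: tuple[tuple[int, ...], ...]
    period: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "period", len(self.states))

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def __contains__(self, state) -> bool:
        return tuple(int(b) for b in state) in self.states


def _boolean_next(net: Network, bits: np.ndarray,
                  act_sets: list[np.ndarray], inh_sets: list[np.ndarray]) -> np.ndarray:
    out = np.zeros_like(bits)
    for i in range(net.n_nodes):
        A, I = act_sets[i], inh_sets[i]
        if A.size == 0 and I.size == 0:
            out[i] = 0
            continue
        act_ok = bool(np.any(bits[A])) if A.size else True
        inh_off = not bool(np.any(bits[I])) if I.size else True
        out[i] = 1 if (act_ok and inh_off) else 0
    return out


def _regulator_index_sets(net: Network):
    acts, inhs = [], []
    for nd in net.nodes:
        a_edges, i_edges = net.regulators(nd.name)
        acts.append(np.array([net.index(e.source) for e in a_edges], dtype=int))
        inhs.append(np.array([net.index(e.source) for e in i_edges], dtype=int))
    return acts, inhs


def boolean_update(net: Network, s, scheme: str = "synchronous",
                   node: str | None = None) -> np.ndarray:
    """One step of the Boolean dynamics.

    Synchronous: all nodes update together.  Asynchronous: only ``node``
    updates; all others keep their value.
    """
    bits = np.asarray(s, dtype=int)
    if bits.shape != (net.n_nodes,):
        raise ValueError(f"state has shape {bits.shape}, expected ({net.n_nodes},)")
    acts, inhs = _regulator_index_sets(net)
    nxt = _boolean_next(net, bits, acts, inhs)
    if scheme == "synchronous":
        return nxt
    if scheme == "asynchronous":
        if node is None:
            raise ValueError("asynchronous update requires a node name")
        i = net.index(node)
        out = bits.copy()
        out[i] = nxt[i]
        return out
    raise ValueError(f"unknown scheme {scheme!r}")


def boolean_attractors(net: Network, max_exhaustive: int = 20,
                       n_samples: int = 1000, seed: int = 0) -> list[BooleanAttractor]:
    """All attractors of the synchronous Boolean map.

    Exact by full state-space enumeration up to ``max_exhaustive`` nodes
    (successor map + pointer doubling); above that, sampled trajectories
    followed to cycle detection.  Attractors are returned with their states
    rotated so the lexicographically smallest state leads, sorted for
    deterministic output.
    """
    N = net.n_nodes
    acts, inhs = _regulator_index_sets(net)
    if N <= max_exhaustive:
        n_states = 1 << N
        # bit i of the state index is node i's value
        bits = ((np.arange(n_states)[:, None] >> np.arange(N)[None, :]) & 1)
        nxt_bits = np.zeros_like(bits)
        for i in range(N):
            A, I = acts[i], inhs[i]
            if A.size == 0 and I.size == 0:
                continue
            ok = np.ones(n_states, dtype=bool)
            if A.size:
                ok &= bits[:, A].any(axis=1)
            if I.size:
                ok &= ~bits[:, I].any(axis=1)
            nxt_bits[:, i] = ok
        succ = (nxt_bits << np.arange(N)[None, :]).sum(axis=1)
        # pointer doubling: succ^(2^k) until k covers the state count
        reach = succ.copy()
        steps = 1
        while steps < n_states:
            reach = reach[reach]
            steps *= 2
        cycle_entry = np.unique(reach)
        seen: set[int] = set()
        attractors = []
        for s0 in cycle_entry:
            if int(s0) in seen:
                continue
            cyc = [int(s0)]
            s = int(succ[s0])
            while s != int(s0):
                cyc.append(s)
                s = int(succ[s])
            seen.update(cyc)
            states = tuple(tuple(int(b) for b in bits[c]) for c in cyc)
            k = min(range(len(states)), key=lambda j: states[j])
            attractors.append(BooleanAttractor(states[k:] + states[:k]))
        return sorted(attractors, key=lambda a: (a.period, a.states))
    # sampled mode for big networks
    rng = np.random.default_rng(seed)
    found: dict[tuple, BooleanAttractor] = {}
    for _ in range(n_samples):
        bitvec = rng.integers(0, 2, size=N)
        seen_states: dict[tuple, int] = {}
        s = bitvec
        step = 0
        while True:
            key = tuple(int(b) for b in s)
            if key in seen_states:
                start = seen_states[key]
                path = list(seen_states)
                cyc = tuple(path[start:])
                k = min(range(len(cyc)), key=lambda j: cyc[j])
                att = BooleanAttractor(cyc[k:] + cyc[:k])
                found[att.states] = att
                break
            seen_states[key] = step
            s = _boolean_next(net, np.array(key), acts, inhs)
            step += 1
    return sorted(found.values(), key=lambda a: (a.period, a.states))


def boolean_state_on_attractor(state, attractors: list[BooleanAttractor]) -> bool:
    """Whether a Boolean state is a state of any listed attractor."""
    key = tuple(int(b) for b in state)
    return any(key in att.states for att in attractors)
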