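"""Independent exhaustive grid-scan oracle for 1-D and 2-D fixed points.

Evaluates the vector field on a regular grid and reports every grid cell
where all components change sign (plus exact zeros at grid points), then
polishes each candidate with scipy's generic root finder.  Shares no code
path with endonet's Newton/integration census.
"""

import numpy as np
from scipy.optimize import brentq, fsolve


def scan_1d(f, step=1e-3):
    """All roots of f on [0, 1] by sign-change scan + bisection."""
    xs = np.arange(0.0, 1.0 + step / 2, step)
    vals = np.array([f(x) for x in xs])
    roots = [float(x) for x, v in zip(xs, vals) if v == 0.0]
    for i in range(len(xs) - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(float(brentq(f, xs[i], xs[i + 1], xtol=1e-12)))
    roots.sort()
    merged = []
    for r in roots:
        if not merged or r - merged[-1] > step / 2:
            merged.append(r)
    return merged


def scan_2d(f, step=1e-3, dedup=1e-3):
    """All zeros of a 2-D vector field on [0,1]^2.

    f maps (x, y) arrays elementwise to (f1, f2) arrays.  Candidate cells
    are those where each component takes both signs among the 4 corners
    (or is exactly zero at a corner); candidates are polished with fsolve.
    """
    xs = np.arange(0.0, 1.0 + step / 2, step)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    F1, F2 = f(X, Y)
    sols = []

    def corners(A):
        return np.stack([A[:-1, :-1], A[1:, :-1], A[:-1, 1:], A[1:, 1:]])

    c1, c2 = corners(F1), corners(F2)
    flip1 = (c1.min(axis=0) <= 0) & (c1.max(axis=0) >= 0)
    flip2 = (c2.min(axis=0) <= 0) & (c2.max(axis=0) >= 0)
    ii, jj = np.nonzero(flip1 & flip2)
    for i, j in zip(ii, jj):
        x0 = np.array([xs[i] + step / 2, xs[j] + step / 2])
        sol, info, ier, _ = fsolve(
            lambda v: np.array(f(v[0], v[1]), dtype=float), x0,
            full_output=True, xtol=1e-12)
        if ier != 1:
            continue
        if np.max(np.abs(np.array(f(sol[0], sol[1])))) > 1e-9:
            continue
        if not np.all((sol > -1e-9) & (sol < 1 + 1e-9)):
            continue
        sol = np.clip(sol, 0.0, 1.0)
        if all(np.max(np.abs(sol - s)) > dedup for s in sols):
            sols.append(sol)
    return sorted(sols, key=lambda s: (round(s[0], 6), round(s[1], 6)))
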