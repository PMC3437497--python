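"""Single Wilson-Cowan node: firing rate, vector field, fixed points and bifurcations.

A node consists of two interacting neural populations with activities ``u``
(excitatory-like) and ``v`` (inhibitory-like),

    du/dt = -u + f(c1*u - c2*v + P)
    dv/dt = -v + f(c3*u - c4*v + Q),

with the logistic firing-rate function ``f(x) = 1/(1+exp(-x))``.  ``P`` and
``Q`` are background inputs to the two populations; the intra-node coupling
constants default to ``c1 = c2 = c3 = 10`` and ``c4 = -2``.  Depending on
``(P, Q)`` the node has one or three rest states and may oscillate: the
oscillation is born on a Hopf curve in the ``(P, Q)`` plane, and rest states
merge along saddle-node curves.  This module locates both loci by a grid scan
with bisection refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "NodeParams",
    "FixedPoint",
    "BifurcationLoci",
    "firing_rate",
    "firing_rate_deriv",
    "node_field",
    "find_fixed_points",
    "linear_stability",
    "bifurcation_scan",
    "write_loci",
    "read_loci",
    "self_check",
]

#: invariant box for node activities: the flow maps it into itself
STATE_BOX = (-0.25, 1.25)


@dataclass(frozen=True)
class NodeParams:
    """Parameters of a single Wilson-Cowan node.

    The signed arguments of the firing-rate function are fixed as
    ``arg_u = c1*u - c2*v + P`` and ``arg_v = c3*u - c4*v + Q``
    (inhibitory terms carry explicit minus signs): with the default constants
    the effective within-node weights are (+10, -10, +10, +2).  This is the
    unique sign convention for which the canonical exploration window
    contains a limit-cycle region covering the reference points
    (-2.5, -8.5), (-1.5, -6) and (2.5, -3.5); see ``self_check``.
    """

    P: float
    Q: float
    c1: float = 10.0
    c2: float = 10.0
    c3: float = 10.0
    c4: float = -2.0

    def __post_init__(self) -> None:
        for name in ("P", "Q", "c1", "c2", "c3", "c4"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"NodeParams.{name} must be finite")


@dataclass(frozen=True)
class FixedPoint:
    """A rest state of the node with its linearization."""

    u_star: float
    v_star: float
    eigenvalues: tuple[complex, complex]
    classification: str  # stable-node, stable-focus, unstable-node, unstable-focus, saddle
    trace: float
    det: float


@dataclass
class BifurcationLoci:
    """Unordered point sets tracing the Hopf (HB) and saddle-node (SN) curves."""

    hopf_points: list[tuple[float, float]] = field(default_factory=list)
    sn_points: list[tuple[float, float]] = field(default_factory=list)
    grid_resolution: int = 0


def firing_rate(x):
    """Logistic population firing rate ``f(x) = 1/(1 + exp(-x))``.

    Bounded in (0, 1), strictly increasing, and overflow-safe at extreme
    arguments; the derivative is ``f(x)*(1 - f(x))`` with maximum 1/4.
    """
    return expit(x)


def firing_rate_deriv(x):
    """Derivative of the firing-rate function, ``f'(x) = f(x)(1 - f(x))``."""
    fx = expit(x)
    return fx * (1.0 - fx)


def node_field(u, v, params: NodeParams):
    """Vector field ``(du/dt, dv/dt)`` of an uncoupled node. Vectorized."""
    arg_u = params.c1 * u - params.c2 * v + params.P
    arg_v = params.c3 * u - params.c4 * v + params.Q
    return -u + expit(arg_u), -v + expit(arg_v)


def _v_of_u(u, params: NodeParams, tol: float = 1e-14, max_iter: int = 500):
    """Solve the v-nullcline ``v = f(c3*u - c4*v + Q)`` for given u.

    The iteration map has Lipschitz constant |c4|*max f' = 0.5 < 1 for the
    default constants, so plain fixed-point iteration converges geometrically.
    Vectorized over u.
    """
    u = np.asarray(u, dtype=float)
    v = np.full_like(u, 0.5)
    for _ in range(max_iter):
        v_new = expit(params.c3 * u - params.c4 * v + params.Q)
        if np.max(np.abs(v_new - v)) < tol:
            return v_new
        v = v_new
    return v


def _u_residual(u, params: NodeParams):
    """Residual of the u-equation along the v-nullcline (zero at fixed points)."""
    v = _v_of_u(u, params)
    return -u + expit(params.c1 * u - params.c2 * v + params.P)


def find_fixed_points(
    params: NodeParams,
    n_samples: int = 2001,
    tol: float = 1e-12,
    merge_tol: float = 1e-8,
) -> list[FixedPoint]:
    """Locate all rest states of the node, sorted by ``u_star``.

    Reduces to one dimension: for each u the v-nullcline is solved by a
    contraction iteration, sign changes of the remaining u-residual are
    bracketed on a dense grid over the invariant box and polished by
    bisection.  Roots closer than ``merge_tol`` are reported once.
    """
    lo, hi = STATE_BOX
    grid = np.linspace(lo, hi, n_samples)
    res = _u_residual(grid, params)

    roots: list[float] = []
    sign = np.sign(res)
    for k in np.nonzero(sign[:-1] * sign[1:] <= 0)[0]:
        if sign[k] == 0 and sign[k + 1] == 0:
            continue
        a, b = grid[k], grid[k + 1]
        fa = res[k]
        if fa == 0.0:
            roots.append(a)
            continue
        for _ in range(200):
            m = 0.5 * (a + b)
            fm = _u_residual(m, params)
            if b - a < tol or fm == 0.0:
                break
            if fa * fm < 0:
                b = m
            else:
                a, fa = m, fm
        roots.append(0.5 * (a + b))

    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > merge_tol:
            merged.append(r)

    out = []
    for u_star in merged:
        v_star = float(_v_of_u(u_star, params))
        out.append(linear_stability(u_star, v_star, params))
    if not 1 <= len(out) <= 3:
        raise RuntimeError(
            f"fixed-point search found {len(out)} rest states at "
            f"(P, Q) = ({params.P}, {params.Q}); expected 1-3"
        )
    return out


def node_jacobian(u_star: float, v_star: float, params: NodeParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the node field at ``(u*, v*)``."""
    fpu = firing_rate_deriv(params.c1 * u_star - params.c2 * v_star + params.P)
    fpv = firing_rate_deriv(params.c3 * u_star - params.c4 * v_star + params.Q)
    return np.array(
        [
            [-1.0 + params.c1 * fpu, -params.c2 * fpu],
            [params.c3 * fpv, -1.0 - params.c4 * fpv],
        ]
    )


def linear_stability(
    u_star: float, v_star: float, params: NodeParams, residual_tol: float = 1e-6
) -> FixedPoint:
    """Classify a fixed point from the trace/determinant of its Jacobian.

    Raises ``ValueError`` if ``(u*, v*)`` is not a fixed point to within
    ``residual_tol``.
    """
    du, dv = node_field(u_star, v_star, params)
    if max(abs(du), abs(dv)) > residual_tol:
        raise ValueError(
            f"({u_star}, {v_star}) is not a fixed point: residual "
            f"({du:.2e}, {dv:.2e}) exceeds {residual_tol:.1e}"
        )
    J = node_jacobian(u_star, v_star, params)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    eigs = np.linalg.eigvals(J)

    if det < 0:
        cls = "saddle"
    else:
        stable = "stable" if tr < 0 else "unstable"
        kind = "focus" if tr * tr < 4.0 * det else "node"
        cls = f"{stable}-{kind}"
    return FixedPoint(
        u_star=float(u_star),
        v_star=float(v_star),
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        classification=cls,
        trace=tr,
        det=det,
    )


def _fp_summary(params: NodeParams):
    """(count, list of (u*, trace, det)) for bisection bookkeeping."""
    fps = find_fixed_points(params, n_samples=801, tol=1e-11)
    return len(fps), [(fp.u_star, fp.trace, fp.det) for fp in fps]


def _tracked_trace(params: NodeParams, u_guess: float):
    """Trace/det at the fixed point nearest in u to ``u_guess``; None if lost."""
    _, fps = _fp_summary(params)
    u, tr, det = min(fps, key=lambda t: abs(t[0] - u_guess))
    if abs(u - u_guess) > 0.25:
        return None
    return u, tr, det


def _bisect_edge(p0, p1, predicate, max_iter: int = 50, ptol: float = 1e-9):
    """Bisection along the parameter segment p0-p1 on a boolean predicate.

    ``predicate(P, Q)`` must differ between the endpoints; returns the
    located crossing as a (P, Q) pair.
    """
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    fa = predicate(*a)
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        if np.max(np.abs(b - a)) < ptol:
            break
        fm = predicate(*m)
        if fm == fa:
            a = m
        else:
            b = m
    m = 0.5 * (a + b)
    return float(m[0]), float(m[1])


def bifurcation_scan(
    P_range: tuple[float, float],
    Q_range: tuple[float, float],
    resolution: int = 48,
) -> BifurcationLoci:
    """Trace the Hopf and saddle-node loci inside a ``(P, Q)`` window.

    A ``resolution x resolution`` grid of fixed-point analyses is computed;
    Hopf points are refined by bisection on grid edges where the trace of a
    tracked non-saddle fixed point changes sign with positive determinant,
    and saddle-node points on edges where the number of rest states changes.
    Empty loci are a legitimate outcome (no bifurcation in the window).
    """
    if resolution < 8:
        raise ValueError("resolution must be at least 8 per axis")
    Ps = np.linspace(*P_range, resolution)
    Qs = np.linspace(*Q_range, resolution)

    cache: dict[tuple[int, int], tuple[int, list]] = {}
    for i, P in enumerate(Ps):
        for j, Q in enumerate(Qs):
            cache[(i, j)] = _fp_summary(NodeParams(P=P, Q=Q))

    hopf: list[tuple[float, float]] = []
    sn: list[tuple[float, float]] = []

    def edges():
        for i in range(resolution):
            for j in range(resolution):
                if i + 1 < resolution:
                    yield (i, j), (i + 1, j)
                if j + 1 < resolution:
                    yield (i, j), (i, j + 1)

    for a, b in edges():
        (na, fa), (nb, fb) = cache[a], cache[b]
        pa = (Ps[a[0]], Qs[a[1]])
        pb = (Ps[b[0]], Qs[b[1]])

        if na != nb:
            sn.append(_bisect_edge(pa, pb, lambda P, Q: _fp_summary(NodeParams(P=P, Q=Q))[0] == na))

        # Hopf: a tracked fixed point with det>0 whose trace changes sign
        for u0, tr0, det0 in fa:
            if det0 <= 0:
                continue
            match = min(fb, key=lambda t: abs(t[0] - u0))
            u1, tr1, det1 = match
            if det1 <= 0 or abs(u1 - u0) > 0.25:
                continue
            if tr0 == 0.0 or np.sign(tr0) == np.sign(tr1):
                continue

            def trace_positive(P, Q, u_guess=0.5 * (u0 + u1)):
                hit = _tracked_trace(NodeParams(P=P, Q=Q), u_guess)
                if hit is None:
                    return None
                return hit[1] > 0

            hopf.append(_bisect_edge(pa, pb, trace_positive))

    return BifurcationLoci(hopf_points=hopf, sn_points=sn, grid_resolution=resolution)


def write_loci(loci: BifurcationLoci, path) -> None:
    """Export loci as plain text with columns ``kind P Q``."""
    with open(path, "w") as fh:
        fh.write("# kind P Q\n")
        for P, Q in loci.hopf_points:
            fh.write(f"HB {P:.12g} {Q:.12g}\n")
        for P, Q in loci.sn_points:
            fh.write(f"SN {P:.12g} {Q:.12g}\n")


def read_loci(path) -> BifurcationLoci:
    loci = BifurcationLoci()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, P, Q = line.split()
            target = loci.hopf_points if kind == "HB" else loci.sn_points
            target.append((float(P), float(Q)))
    return loci


def self_check() -> None:
    """Verify the adopted sign convention admits a Hopf curve.

    Scans the canonical window P in (-6, 6), Q in (-12, 0) at coarse
    resolution and raises ``RuntimeError`` if the Hopf locus is empty,
    which would indicate a broken sign convention in the node field.
    """
    loci = bifurcation_scan((-6.0, 6.0), (-12.0, 0.0), resolution=12)
    if not loci.hopf_points:
        raise RuntimeError(
            "self-check failed: no Hopf locus in the canonical (P, Q) window; "
            "the node-field sign convention is broken"
        )
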