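"""Weakly-coupled-oscillator machinery: limit cycle, adjoint, H(theta), synchrony stability.

The coupled network is first transformed to coordinates in which the
coupling enters additively: with ``x = c1*u - c2*v + P + coupling`` and
``y = c3*u - c4*v + Q`` each node obeys

    dx/dt = -x + P + c1*f(x) - c2*f(y) + eps * sum_j w_ij * f(x_j)
    dy/dt = -y + Q + c3*f(x) - c4*f(y).

For weak coupling, each oscillatory node is reduced to a single phase
``theta in [0, 1)`` with intrinsic drift ``1/T``.  The phase-response
(adjoint) vector ``Z`` of the T-periodic orbit is computed by backward
integration of the adjoint equation and normalized so ``Z . F = 1/T``.
Because the coupling perturbs only the x-equation, the 1-periodic phase
interaction function is

    H(theta) = (1/T) * int_0^T Z_x(s) * f(x(s + theta*T)) ds,

and the synchronous network state is stable precisely when all nonzero
eigenvalues of the phase-locking Jacobian
``eps*H'(0)*(w_ij - delta_ij*sum_k w_ik)`` have negative real part; for any
connected row-normalized coupling matrix this reduces to the sign of
``H'(0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.special import expit

from .connectome import StructuralConnectivity
from .node_model import NodeParams, firing_rate_deriv

__all__ = [
    "NoLimitCycleError",
    "LimitCycle",
    "AdjointOrbit",
    "PhaseInteraction",
    "PhaseLockJacobian",
    "transformed_field",
    "transform_uv_to_xy",
    "find_limit_cycle",
    "adjoint",
    "interaction_function",
    "sync_jacobian",
    "hprime_map",
    "hprime_at",
]


class NoLimitCycleError(RuntimeError):
    """Raised when no attracting periodic orbit exists at the given parameters."""


@dataclass
class LimitCycle:
    """Attracting T-periodic orbit of the transformed node, uniformly sampled."""

    T: float
    x: np.ndarray  # M samples over one period
    y: np.ndarray
    params: NodeParams
    closure_error: float = 0.0
    amplitude: float = 0.0

    @property
    def M(self) -> int:
        return len(self.x)


@dataclass
class AdjointOrbit:
    """Phase-response vector Z = (Z_x, Z_y) aligned with the limit-cycle samples."""

    Zx: np.ndarray
    Zy: np.ndarray
    periodicity_error: float = 0.0
    normalization_error: float = 0.0


@dataclass
class PhaseInteraction:
    """Sampled 1-periodic interaction function H(theta) and its slope at zero."""

    theta: np.ndarray
    H: np.ndarray
    H_prime_0: float
    T: float


@dataclass
class PhaseLockJacobian:
    """Linearization of the phase equations at a phase-locked state."""

    matrix: np.ndarray
    eigenvalues: np.ndarray  # sorted by real part, ascending
    stable: bool
    in_units_of_eps_hprime: bool = False


def transformed_field(x, y, params: NodeParams):
    """Vector field of the transformed (additively-coupled) node. Vectorized."""
    fx = expit(x)
    fy = expit(y)
    dx = -x + params.P + params.c1 * fx - params.c2 * fy
    dy = -y + params.Q + params.c3 * fx - params.c4 * fy
    return dx, dy


def transform_uv_to_xy(u, v, params: NodeParams):
    """Map original node coordinates to transformed ones (uncoupled node)."""
    x = params.c1 * u - params.c2 * v + params.P
    y = params.c3 * u - params.c4 * v + params.Q
    return x, y


def _transformed_jacobian(x, y, params: NodeParams) -> np.ndarray:
    fpx = firing_rate_deriv(x)
    fpy = firing_rate_deriv(y)
    return np.array(
        [
            [-1.0 + params.c1 * fpx, -params.c2 * fpy],
            [params.c3 * fpx, -1.0 - params.c4 * fpy],
        ]
    )


def find_limit_cycle(
    params: NodeParams,
    M: int = 1024,
    transient: float = 500.0,
    min_amplitude: float = 1e-4,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> LimitCycle:
    """Locate the attracting periodic orbit of the transformed node.

    Long integration past the transient, then period detection on a
    Poincare section (upward crossing of x through its orbit mean, with
    solver event root-finding), then resampling to ``M`` uniform points.
    Raises :class:`NoLimitCycleError` when the trajectory settles to rest.
    """
    x0, y0 = transform_uv_to_xy(0.3, 0.2, params)
    rhs = lambda t, s: transformed_field(s[0], s[1], params)

    sol = solve_ivp(rhs, (0.0, transient), [x0, y0], rtol=rtol, atol=atol)
    s0 = sol.y[:, -1]

    probe_span = 200.0
    probe = solve_ivp(rhs, (0.0, probe_span), s0, rtol=rtol, atol=atol, dense_output=True)
    tt = np.linspace(0.25 * probe_span, probe_span, 4000)
    xs = probe.sol(tt)[0]
    amplitude = float(xs.max() - xs.min())
    if amplitude < min_amplitude:
        raise NoLimitCycleError(
            f"no oscillation at (P, Q) = ({params.P}, {params.Q}): "
            f"amplitude {amplitude:.2e} below {min_amplitude:.0e}"
        )
    x_mean = float(xs.mean())

    # rough period estimate from the probe's upward mean-crossings sets the
    # span of the event-refined integration
    up = np.nonzero((xs[:-1] < x_mean) & (xs[1:] >= x_mean))[0]
    if len(up) < 3:
        # fewer than 3 cycles in the probe window: very long period, re-probe
        probe_span = 2000.0
        probe = solve_ivp(rhs, (0.0, probe_span), s0, rtol=rtol, atol=atol, dense_output=True)
        tt = np.linspace(0.25 * probe_span, probe_span, 20000)
        xs = probe.sol(tt)[0]
        x_mean = float(xs.mean())
        up = np.nonzero((xs[:-1] < x_mean) & (xs[1:] >= x_mean))[0]
        if len(up) < 3:
            raise NoLimitCycleError(
                f"no repeating oscillation at (P, Q) = ({params.P}, {params.Q})"
            )
    T_est = float(np.median(np.diff(tt[up])))

    section = lambda t, s: s[0] - x_mean
    section.direction = 1.0
    ev = solve_ivp(
        rhs,
        (0.0, 12.0 * T_est),
        probe.sol(probe_span),
        rtol=rtol,
        atol=atol,
        events=section,
        dense_output=True,
    )
    crossings = ev.t_events[0]
    if len(crossings) < 4:
        raise NoLimitCycleError(
            f"fewer than 4 section crossings at (P, Q) = ({params.P}, {params.Q})"
        )
    periods = np.diff(crossings[-8:]) if len(crossings) >= 8 else np.diff(crossings)
    T = float(np.median(periods))

    t0 = crossings[-2]
    samples = ev.sol(t0 + np.arange(M) * (T / M))
    closure = float(np.linalg.norm(ev.sol(t0) - ev.sol(t0 + T)))
    return LimitCycle(
        T=T,
        x=samples[0],
        y=samples[1],
        params=params,
        closure_error=closure,
        amplitude=amplitude,
    )


def _periodic_orbit_spline(lc: LimitCycle):
    t = np.linspace(0.0, lc.T, lc.M + 1)
    vals = np.column_stack(
        [np.append(lc.x, lc.x[0]), np.append(lc.y, lc.y[0])]
    )
    return CubicSpline(t, vals, bc_type="periodic")


def adjoint(
    lc: LimitCycle,
    params: NodeParams | None = None,
    n_periods: int = 25,
    conv_tol: float = 1e-8,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> AdjointOrbit:
    """Phase-response vector by backward integration of the adjoint equation.

    ``dZ/dt = -J(t)^T Z`` is integrated backwards (the periodic adjoint
    solution is attracting in reverse time) over at least 20 periods until
    the per-period change falls below ``conv_tol``, then scaled so that
    ``Z(t) . F(t) = 1/T`` (phase theta in [0, 1), drift 1/T).
    """
    params = params or lc.params
    orbit = _periodic_orbit_spline(lc)
    T = lc.T

    def rhs(t, Z):
        xy = orbit(t % T)
        J = _transformed_jacobian(xy[0], xy[1], params)
        return -J.T @ Z

    n_periods = max(n_periods, 20)
    t_hi = n_periods * T
    sol = solve_ivp(
        rhs,
        (t_hi, 0.0),
        [1.0, 0.0],
        rtol=rtol,
        atol=atol,
        dense_output=True,
        t_eval=None,
    )

    # per-period convergence of the direction of Z at phase 0
    def unit(z):
        nrm = np.linalg.norm(z)
        return z / nrm if nrm > 0 else z

    conv = np.inf
    for k in range(1, n_periods):
        za = unit(sol.sol(k * T))
        zb = unit(sol.sol((k - 1) * T))
        conv = min(conv, float(np.linalg.norm(za - np.sign(za @ zb) * zb)))
    if conv > conv_tol:
        raise RuntimeError(
            f"adjoint iteration did not converge: per-period change {conv:.2e} "
            f"> {conv_tol:.0e} after {n_periods} periods (weak attraction?)"
        )

    ts = np.arange(lc.M) * (T / lc.M)
    Z = sol.sol(ts)  # shape (2, M)
    F = np.array(transformed_field(lc.x, lc.y, params))
    zf = np.einsum("km,km->m", Z, F)
    scale = 1.0 / (T * np.mean(zf))
    Z = Z * scale
    zf_n = np.einsum("km,km->m", Z, F) * T  # should be 1 everywhere
    norm_err = float(np.max(np.abs(zf_n - 1.0)))
    per_err = float(np.linalg.norm(unit(sol.sol(0.0)) - unit(sol.sol(T))))
    return AdjointOrbit(
        Zx=Z[0], Zy=Z[1], periodicity_error=per_err, normalization_error=norm_err
    )


def interaction_function(lc: LimitCycle, adj: AdjointOrbit) -> PhaseInteraction:
    """H(theta) and H'(0) from aligned limit-cycle and adjoint samples.

    ``H(theta) = (1/T) int_0^T Z_x(s) f(x(s + theta*T)) ds`` evaluated by
    uniform-grid quadrature at the M sample phases; ``H'(0)`` by the direct
    quadrature of ``Z_x(s) f'(x(s)) x'(s)`` (no differentiation of sampled
    H data).
    """
    if len(adj.Zx) != lc.M:
        raise ValueError("adjoint and limit-cycle sample grids are misaligned")
    M = lc.M
    g = expit(lc.x)  # f(x(s))
    # circular cross-correlation via FFT: H[m] = (1/M) sum_k Zx[k] g[(k+m) % M]
    H = np.real(np.fft.ifft(np.conj(np.fft.fft(adj.Zx)) * np.fft.fft(g))) / M
    theta = np.arange(M) / M

    xdot, _ = transformed_field(lc.x, lc.y, lc.params)
    integrand = adj.Zx * firing_rate_deriv(lc.x) * xdot
    H_prime_0 = float(np.sum(integrand) * (lc.T / M))
    return PhaseInteraction(theta=theta, H=H, H_prime_0=H_prime_0, T=lc.T)


def hprime_spectral(pi: PhaseInteraction) -> float:
    """H'(0) by spectral differentiation of the sampled H; cross-check route."""
    M = len(pi.H)
    k = np.fft.fftfreq(M, d=1.0 / M)
    dH = np.real(np.fft.ifft(2j * np.pi * k * np.fft.fft(pi.H)))
    return float(dH[0])


def sync_jacobian(
    sc: StructuralConnectivity | np.ndarray,
    h_prime_0: float = 1.0,
    epsilon: float = 1.0,
    in_units_of_eps_hprime: bool = False,
) -> PhaseLockJacobian:
    """Jacobian of the phase equations at the synchronous state.

    Entries are ``eps * H'(0) * (w_ij - delta_ij * sum_k w_ik)``; rows sum
    to zero, so one eigenvalue is always 0.  The synchronous state is
    stable iff all remaining eigenvalues have negative real part.  With
    ``in_units_of_eps_hprime`` the prefactor is dropped (scale-free form).
    """
    w = sc.w if isinstance(sc, StructuralConnectivity) else np.asarray(sc, dtype=float)
    scale = 1.0 if in_units_of_eps_hprime else epsilon * h_prime_0
    mat = scale * (w - np.diag(w.sum(axis=1)))
    eigs = np.linalg.eigvals(mat)
    eigs = eigs[np.argsort(eigs.real)]
    # discard the structural zero eigenvalue (smallest modulus), judge the rest
    nz = np.delete(eigs, np.argmin(np.abs(eigs)))
    stable = bool(np.all(nz.real < 1e-9)) if len(nz) else True
    return PhaseLockJacobian(
        matrix=mat,
        eigenvalues=eigs,
        stable=stable,
        in_units_of_eps_hprime=in_units_of_eps_hprime,
    )


def hprime_at(P: float, Q: float, M: int = 1024, **node_kwargs) -> float:
    """H'(0) of the uncoupled node at one parameter point.

    Raises :class:`NoLimitCycleError` outside the oscillatory region.
    """
    params = NodeParams(P=P, Q=Q, **node_kwargs)
    lc = find_limit_cycle(params, M=M)
    adj = adjoint(lc)
    return interaction_function(lc, adj).H_prime_0


def hprime_map(
    P_range: tuple[float, float],
    Q_range: tuple[float, float],
    resolution: int | tuple[int, int] = 13,
    M: int = 512,
) -> dict:
    """Grid of H'(0) over a (P, Q) window; NaN where no limit cycle exists.

    ``resolution`` is points per axis (one int, or (nP, nQ)).  Returns a
    dict with 1-D ``P``, ``Q`` axes, a (len(Q), len(P)) array ``hprime``
    and a same-shaped object array ``status`` taking values "ok",
    "no-limit-cycle" or "failed: ...".  Individual-point failures are
    recorded, never fatal.
    """
    nP, nQ = (resolution, resolution) if isinstance(resolution, int) else resolution
    Ps = np.linspace(*P_range, nP)
    Qs = np.linspace(*Q_range, nQ)
    hp = np.full((nQ, nP), np.nan)
    status = np.empty((nQ, nP), dtype=object)
    for j, Q in enumerate(Qs):
        for i, P in enumerate(Ps):
            try:
                hp[j, i] = hprime_at(P, Q, M=M)
                status[j, i] = "ok"
            except NoLimitCycleError:
                status[j, i] = "no-limit-cycle"
            except Exception as exc:  # pragma: no cover - defensive
                status[j, i] = f"failed: {exc}"
    return {"P": Ps, "Q": Qs, "hprime": hp, "status": status}


def period_survey(
    P_range: tuple[float, float] = (-6.0, 6.0),
    Q_range: tuple[float, float] = (-12.0, 0.0),
    resolution: int = 13,
    refine_boundary: bool = True,
    n_refine: int = 10,
    M: int = 128,
) -> list[tuple[float, float, float]]:
    """Survey limit-cycle periods over a (P, Q) window.

    Returns (P, Q, T) records for every oscillatory grid point.  With
    ``refine_boundary`` the survey additionally bisects along each Q-row
    between the last oscillatory and first quiescent P, recording the probe
    periods: the oscillation dies there in a saddle-node-on-invariant-circle
    scenario with diverging period, so the long-period tail of the region
    lives in a narrow band near this boundary.
    """
    fast = dict(M=M, rtol=1e-7, atol=1e-9, transient=300.0)
    Ps = np.linspace(*P_range, resolution)
    Qs = np.linspace(*Q_range, resolution)
    records: list[tuple[float, float, float]] = []
    for Q in Qs:
        row: list[tuple[float, bool]] = []
        for P in Ps:
            try:
                lc = find_limit_cycle(NodeParams(P=P, Q=Q), **fast)
                records.append((float(P), float(Q), lc.T))
                row.append((float(P), True))
            except NoLimitCycleError:
                row.append((float(P), False))
        if not refine_boundary:
            continue
        for (P0, osc0), (P1, osc1) in zip(row[:-1], row[1:]):
            if osc0 == osc1:
                continue
            lo, hi = (P0, P1) if osc0 else (P1, P0)  # lo oscillatory
            for _ in range(n_refine):
                mid = 0.5 * (lo + hi)
                try:
                    lc = find_limit_cycle(NodeParams(P=mid, Q=Q), **fast)
                    records.append((float(mid), float(Q), lc.T))
                    lo = mid
                except NoLimitCycleError:
                    hi = mid
    return records


def write_hprime_map(result: dict, path) -> None:
    """Export an H'(0) map as tabular text: P Q Hprime0 status."""
    with open(path, "w") as fh:
        fh.write("# P Q Hprime0 status\n")
        for j, Q in enumerate(result["Q"]):
            for i, P in enumerate(result["P"]):
                h = result["hprime"][j, i]
                fh.write(f"{P:.6g} {Q:.6g} {h:.10g} {result['status'][j, i]}\n")
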