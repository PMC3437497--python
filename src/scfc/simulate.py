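"""Euler-Maruyama integration of the coupled Wilson-Cowan network.

The network equations for node ``i`` are

    du_i/dt = -u_i + f(c1*u_i - c2*v_i + P_i + eps * sum_j w_ij * u_j) + noise
    dv_i/dt = -v_i + f(c3*u_i - c4*v_i + Q)

integrated with the explicit Euler-Maruyama scheme: deterministic drift step
``dt`` plus ``noise_sigma * sqrt(dt)`` Gaussian increments applied to the
``u`` variable of each node independently.  The default protocol is a run of
10 000 time units at ``dt = 0.1`` with the first 1000 time units discarded
as transient, random initial conditions uniform on (0, 1), coupling
``eps = 1`` and ``noise_sigma = 0.01``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .connectome import StructuralConnectivity
from .node_model import NodeParams

__all__ = ["SimConfig", "TimeSeriesSet", "integrate", "drop_transient"]

_BLOWUP_LIMIT = 10.0


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol parameters.

    ``noise_sigma`` is the diffusion amplitude multiplying ``sqrt(dt)*xi``
    in the Euler-Maruyama update.  ``p_jitter_range``, when set, draws one
    quenched per-node offset for ``P`` uniformly from the given interval at
    the start of the run (the node-heterogeneity variant, canonical interval
    (0, 0.01)).
    """

    epsilon: float = 1.0
    noise_sigma: float = 0.01
    dt: float = 0.1
    t_total: float = 10_000.0
    t_transient: float = 1000.0
    seed: int | None = None
    p_jitter_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.t_transient < self.t_total:
            raise ValueError("need 0 <= t_transient < t_total")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class TimeSeriesSet:
    """Simulated node trajectories on a uniform time grid.

    ``u`` and ``v`` have shape (n_nodes, n_samples); sample ``k`` is at time
    ``t0 + k*dt``.
    """

    u: np.ndarray
    v: np.ndarray
    dt: float
    t0: float
    params: NodeParams
    config: SimConfig
    sc_label: str = ""

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shapes")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("non-finite values in time series")

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]

    @property
    def duration(self) -> float:
        return self.u.shape[1] * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.u.shape[1])

    def export_text(self, path) -> None:
        """Plain-text export: one row per sample, columns t, u_0..u_{n-1}."""
        data = np.column_stack([self.times, self.u.T])
        header = "t " + " ".join(f"u_{i}" for i in range(self.n_nodes))
        np.savetxt(path, data, header=header)


def integrate(
    sc: StructuralConnectivity, params: NodeParams, config: SimConfig
) -> TimeSeriesSet:
    """Integrate the coupled network; fully reproducible under a fixed seed.

    Initial conditions are uniform on (0, 1) for both variables of every
    node; noise is applied to ``u`` only, independently per node and step.
    Raises ``RuntimeError`` on numerical blow-up (|u| > 10), which does not
    occur in the canonical parameter window.
    """
    rng = np.random.default_rng(config.seed)
    n = sc.n
    n_steps = int(round(config.t_total / config.dt))
    c1, c2, c3, c4 = params.c1, params.c2, params.c3, params.c4

    P = np.full(n, params.P)
    if config.p_jitter_range is not None:
        lo, hi = config.p_jitter_range
        P = P + rng.uniform(lo, hi, size=n)
    Q = params.Q

    u = rng.uniform(0.0, 1.0, size=n)
    v = rng.uniform(0.0, 1.0, size=n)
    dt = config.dt
    sq = config.noise_sigma * np.sqrt(dt)
    w = sc.w
    eps = config.epsilon

    U = np.empty((n, n_steps + 1))
    V = np.empty((n, n_steps + 1))
    U[:, 0] = u
    V[:, 0] = v

    # pre-drawn noise: one generator call, keeps the step loop cheap
    noise = rng.standard_normal((n_steps, n)) if sq > 0 else None

    for k in range(n_steps):
        arg_u = c1 * u - c2 * v + P + eps * (w @ u)
        arg_v = c3 * u - c4 * v + Q
        du = -u + expit(arg_u)
        dv = -v + expit(arg_v)
        u = u + dt * du
        if noise is not None:
            u = u + sq * noise[k]
        v = v + dt * dv
        U[:, k + 1] = u
        V[:, k + 1] = v
        if k % 1000 == 0 and np.max(np.abs(u)) > _BLOWUP_LIMIT:
            raise RuntimeError(
                f"numerical blow-up at t={k * dt:.1f}: max |u| = {np.max(np.abs(u)):.3g} "
                f"(P={params.P}, Q={params.Q}, eps={eps}, dt={dt})"
            )

    ts = TimeSeriesSet(
        u=U, v=V, dt=dt, t0=0.0, params=params, config=config, sc_label=sc.label
    )
    return ts


def drop_transient(ts: TimeSeriesSet, t_transient: float | None = None) -> TimeSeriesSet:
    """Discard the initial transient; retained samples start at ``t_transient``."""
    if t_transient is None:
        t_transient = ts.config.t_transient
    if t_transient < 0 or t_transient >= ts.duration:
        raise ValueError(
            f"transient {t_transient} must lie in [0, duration={ts.duration})"
        )
    k0 = int(round(t_transient / ts.dt))
    return TimeSeriesSet(
        u=ts.u[:, k0:],
        v=ts.v[:, k0:],
        dt=ts.dt,
        t0=ts.t0 + k0 * ts.dt,
        params=ts.params,
        config=ts.config,
        sc_label=ts.sc_label,
    )
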