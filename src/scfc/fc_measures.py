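"""Functional connectivity from time series: Pearson correlation and mean phase coherence.

Mean phase coherence of two signals is the modulus of the time-averaged unit
phasor of their instantaneous phase difference,

    R_ij = | <exp(i * (phi_i(t) - phi_j(t)))>_t |  in [0, 1],

with instantaneous phases read off the analytic signal (Hilbert transform)
of each mean-centred series.  It is 1 for perfectly phase-locked signals at
any fixed lag (including anti-phase, where Pearson correlation is -1) and
decays like n^(-1/2) for independent phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .simulate import TimeSeriesSet

__all__ = [
    "FCMatrix",
    "pearson_fc",
    "instantaneous_phase",
    "mean_phase_coherence_fc",
]

#: fraction of samples trimmed at each record boundary before averaging
#: phase differences (Gibbs ringing of the analytic signal at the edges)
EDGE_TRIM = 0.05


@dataclass
class FCMatrix:
    """Symmetric node x node functional-connectivity matrix."""

    values: np.ndarray
    measure: str  # "correlation" | "mean_phase_coherence"
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def export_text(self, path) -> None:
        np.savetxt(
            path,
            self.values,
            header=f"measure={self.measure} source={self.source}",
        )


def _series_matrix(ts) -> np.ndarray:
    if isinstance(ts, TimeSeriesSet):
        return ts.u
    return np.atleast_2d(np.asarray(ts, dtype=float))


def pearson_fc(ts: TimeSeriesSet | np.ndarray) -> FCMatrix:
    """Product-moment correlation of all u-series pairs.

    Constant series have undefined correlation; their entries are set to 0
    with a warning (diagonal stays 1).
    """
    x = _series_matrix(ts)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    constant = np.flatnonzero(x.std(axis=1) == 0)
    if constant.size:
        warnings.warn(
            f"constant series at nodes {constant.tolist()}: correlation undefined, set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c[np.isnan(c)] = 0.0
    np.fill_diagonal(c, 1.0)
    source = ts.sc_label if isinstance(ts, TimeSeriesSet) else ""
    return FCMatrix(values=np.clip(c, -1.0, 1.0), measure="correlation", source=source)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of one or more series via the analytic signal.

    Input rows are mean-centred before the Hilbert transform (the phase of a
    nonzero-mean analytic signal is ill-defined); output phases are wrapped
    to (-pi, pi].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] < 16:
        raise ValueError("need at least 16 samples for a meaningful analytic signal")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant series has no instantaneous phase")
    centred = x - x.mean(axis=1, keepdims=True)
    phi = np.angle(hilbert(centred, axis=1))
    return phi if x.shape[0] > 1 else phi


def mean_phase_coherence_fc(
    ts: TimeSeriesSet | np.ndarray, edge_trim: float = EDGE_TRIM
) -> FCMatrix:
    """Mean phase coherence between all u-series pairs.

    The first and last ``edge_trim`` fraction of phase samples are excluded
    from the average to suppress boundary artefacts of the Hilbert
    transform.
    """
    x = _series_matrix(ts)
    phi = instantaneous_phase(x)
    n_t = phi.shape[1]
    k = int(np.floor(edge_trim * n_t))
    core = phi[:, k : n_t - k] if k > 0 else phi
    z = np.exp(1j * core)
    # R_ij = |mean_t z_i * conj(z_j)|
    r = np.abs(z @ z.conj().T) / core.shape[1]
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    source = ts.sc_label if isinstance(ts, TimeSeriesSet) else ""
    return FCMatrix(values=np.clip(r, 0.0, 1.0), measure="mean_phase_coherence", source=source)
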