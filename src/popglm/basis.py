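"""Nonlinearly time-scaled raised-cosine temporal bases.

Kernels of the encoding model (target, saccade, spike-history, coupling) are
parameterized as weighted sums of raised-cosine bumps whose peaks are evenly
spaced in log-warped time, so early lags are finely resolved and late lags
coarsely.  Column j is

    b_j(t) = (1 + cos(u_j(t))) / 2   for |u_j(t)| <= pi, else 0,
    u_j(t) = (log(t + a) - phi_j) * pi / delta,

with warp offset ``a`` (ms), peak positions ``phi_j`` evenly spaced in the
warped axis, and ``delta`` the peak spacing.  Each column is normalized to a
peak value of 1, so a weight reads directly as a log-gain amplitude.

History and coupling bases are strictly causal (support starts at lag 1 bin,
``lag0_inclusive=False``); task-event bases may include lag 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BasisSet", "make_raised_cosine_basis", "reconstruct_kernel",
           "basis_convolve", "project_kernel"]


@dataclass
class BasisSet:
    n_basis: int
    window_ms: float
    warp_offset: float
    B: np.ndarray  # (n_lags, n_basis); row i is lag (i + lag_offset) ms
    lag0_inclusive: bool
    peaks_ms: np.ndarray

    @property
    def n_lags(self) -> int:
        return self.B.shape[0]

    @property
    def lag_offset(self) -> int:
        """First lag (in bins) covered by row 0 of B."""
        return 0 if self.lag0_inclusive else 1

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(self.n_lags) + self.lag_offset


def make_raised_cosine_basis(n_basis: int, window_ms: float,
                             warp_offset: float = 10.0,
                             lag0_inclusive: bool = False,
                             first_peak_ms: float | None = None,
                             last_peak_ms: float | None = None) -> BasisSet:
    """Build a log-warped raised-cosine basis on a 1 ms lag grid.

    Defaults place the first peak at the first lag of the support and the
    last peak at 60% of the window, which leaves the last bump decaying to
    ~0 near the window end for typical warp offsets.
    """
    if n_basis < 2:
        raise ValueError("n_basis must be >= 2")
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if warp_offset <= 0:
        raise ValueError("warp_offset must be positive")
    lag_offset = 0 if lag0_inclusive else 1
    if first_peak_ms is None:
        first_peak_ms = float(lag_offset) + 1.0
    if last_peak_ms is None:
        last_peak_ms = 0.6 * window_ms
    if not (0 <= first_peak_ms < last_peak_ms <= window_ms):
        raise ValueError("need 0 <= first_peak < last_peak <= window")

    def warp(t):
        return np.log(np.asarray(t, dtype=float) + warp_offset)

    phis = np.linspace(warp(first_peak_ms), warp(last_peak_ms), n_basis)
    delta = phis[1] - phis[0]
    if delta <= 0:
        raise ValueError(
            f"window {window_ms} ms too short for {n_basis} distinct peaks")
    lags = np.arange(int(round(window_ms))) + lag_offset
    lags = lags[lags <= window_ms]
    u = (warp(lags)[:, None] - phis[None, :]) * np.pi / delta
    B = 0.5 * (1 + np.cos(np.clip(u, -np.pi, np.pi)))
    B[np.abs(u) > np.pi] = 0.0
    # normalize each column to peak 1 on the evaluated lag grid
    colmax = B.max(axis=0)
    if np.any(colmax <= 0):
        raise ValueError("degenerate basis column (empty support)")
    B = B / colmax
    peaks_ms = np.exp(phis) - warp_offset
    return BasisSet(n_basis=n_basis, window_ms=float(window_ms),
                    warp_offset=float(warp_offset), B=B,
                    lag0_inclusive=lag0_inclusive, peaks_ms=peaks_ms)


def reconstruct_kernel(basis: BasisSet, weights: np.ndarray) -> np.ndarray:
    """Time-domain kernel (log-gain per 1 ms bin over the support)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (basis.n_basis,):
        raise ValueError(
            f"expected {basis.n_basis} weights, got shape {weights.shape}")
    return basis.B @ weights


def project_kernel(basis: BasisSet, kernel: np.ndarray) -> np.ndarray:
    """Least-squares weights whose reconstruction best matches ``kernel``.

    ``kernel`` is sampled on the basis lag grid (padded/truncated to fit).
    Inverse of :func:`reconstruct_kernel` for kernels in span(B).
    """
    k = np.zeros(basis.n_lags)
    m = min(len(kernel), basis.n_lags)
    k[:m] = np.asarray(kernel, dtype=float)[:m]
    w, *_ = np.linalg.lstsq(basis.B, k, rcond=None)
    return w


def basis_convolve(event_train: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Convolve a per-bin event/count train with every basis column.

    Output row t, column j is ``sum_tau event[t - tau] * b_j(tau)`` with tau
    running over the basis support (lags >= 1 for causal bases).  The
    convolution never crosses the array boundary, so callers convolve each
    trial separately and no leakage across trials can occur.
    """
    ev = np.asarray(event_train, dtype=float)
    if ev.ndim != 1:
        raise ValueError("event_train must be 1-D")
    T = ev.size
    off = basis.lag_offset
    out = np.zeros((T, basis.n_basis))
    if T == 0:
        return out
    for j in range(basis.n_basis):
        full = np.convolve(ev, basis.B[:, j])
        out[off:, j] = full[:T - off] if off else full[:T]
    return out
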