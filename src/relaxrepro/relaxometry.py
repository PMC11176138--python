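"""Voxel-wise mono-exponential decay fitting for T2/T2* parametric maps.

The signal model is

    S(t) = A + S0 * exp(-t / T)

with A an absolute bias (noise-floor offset), S0 the initial signal
intensity and T the transverse relaxation time (T2 or T2*) in
milliseconds.  Fitting minimizes the sum of squared residuals over
(A, S0, T) subject to A >= 0, S0 >= 0 and T in [0.1, 1000] ms.

The minimizer uses variable projection: for fixed T the model is linear in
(A, S0), so the non-negative linear subproblem is solved exactly in closed
form (interior solution or the best feasible edge), leaving a 1-D profile
objective in T that is scanned on a log-spaced grid and refined by
golden-section search.  This is exact for noiseless data, never worse than
a grid search by construction, and vectorizes over whole volumes.
Boundary-pinned T or a vanishing S0 (non-identifiable decay) is reported
as non-convergence; invalid voxels propagate as NaN, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel

from .acquisition import EchoSeries
from .protocols import Protocol

__all__ = [
    "DecayParams",
    "FitResult",
    "FitOptions",
    "ParametricMap",
    "decay_signal",
    "loglinear_init",
    "fit_voxel",
    "fit_map",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0  # inverse golden ratio


@dataclass(frozen=True)
class DecayParams:
    """Decay-model parameters: offset A, initial signal S0, relaxation time T (ms)."""

    A: float
    S0: float
    T: float


@dataclass(frozen=True)
class FitResult:
    """Outcome of one voxel fit; ``converged=False`` params must be excluded downstream."""

    params: DecayParams
    converged: bool
    rss: float
    n_echoes_used: int


class FitOptions(BaseModel):
    """Fit configuration.

    ``t_bounds`` (ms) covers the observed tumor/muscle range (~10-65 ms)
    with wide margin; ``grid_size`` log-spaced profile-scan points;
    ``xtol`` relative convergence tolerance on T; ``fit_offset=False``
    pins A = 0 (two-parameter model).
    """

    t_bounds: tuple[float, float] = (0.1, 1000.0)
    grid_size: int = 64
    xtol: float = 1e-10
    max_iter: int = 200
    fit_offset: bool = True


def decay_signal(params: DecayParams, echo_times: np.ndarray) -> np.ndarray:
    """Evaluate S(t) = A + S0*exp(-t/T) at the given echo times (ms)."""
    te = np.asarray(echo_times, dtype=float)
    if np.any(te <= 0):
        raise ValueError("echo times must be > 0")
    if params.T <= 0:
        raise ValueError(f"relaxation time must be > 0, got {params.T}")
    return params.A + params.S0 * np.exp(-te / params.T)


def loglinear_init(signal: np.ndarray, echo_times: np.ndarray) -> DecayParams | None:
    """Log-linear seed estimate of (A, S0, T).

    The offset is approximated by the minimum over the last quartile of
    echoes (floored at 0), subtracted, and a least-squares line is fit to
    log(signal - A) versus t; T = -1/slope (clamped to [0.1, 1000] ms) and
    S0 = exp(intercept).  Returns ``None`` when the voxel is degenerate
    (non-finite, all-zero, or non-decaying signal), flagging it unfit.
    """
    y = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if y.size < 3:
        raise ValueError("at least 3 echoes required")
    if not np.all(np.isfinite(y)) or np.all(y == 0):
        return None
    n_tail = max(1, y.size // 4)
    tail_min = max(float(np.min(y[-n_tail:])), 0.0)
    best: DecayParams | None = None
    best_rss = np.inf
    for a_hat in {0.0, tail_min}:
        resid = y - a_hat
        peak = float(resid.max())
        if peak <= 0:
            continue
        # drop samples consumed by the offset estimate (log would explode)
        use = resid > max(0.15 * peak, 1e-12)
        if use.sum() < 2:
            continue
        slope, intercept = np.polyfit(te[use], np.log(resid[use]), 1)
        if slope >= -1e-6:  # flat: T non-identifiable
            continue
        t_hat = float(np.clip(-1.0 / slope, 0.1, 1000.0))
        s0_hat = float(np.exp(intercept))
        rss = float(np.sum((a_hat + s0_hat * np.exp(-te / t_hat) - y) ** 2))
        if rss < best_rss:
            best_rss = rss
            best = DecayParams(A=a_hat, S0=s0_hat, T=t_hat)
    return best


def _nnls2(Sy, Syy, Se, See, Sey, m, fit_offset):
    """Best (A, S0) and RSS of the linear subproblem at fixed T.

    Inputs are the sufficient statistics (broadcastable arrays); solves
    min ||A + S0*e - y||^2 subject to A, S0 >= 0 exactly: the interior
    2x2 solution when feasible, else the better of the A=0 / S0=0 edges.
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # edge A = 0 (degenerate See, from exp underflow at tiny T, -> S0 = 0)
        s0_e1 = np.where(See > 0, np.maximum(Sey / np.where(See > 0, See, 1.0), 0.0), 0.0)
        rss_e1 = Syy - 2.0 * s0_e1 * Sey + s0_e1**2 * See
    rss_e1 = np.where(np.isfinite(rss_e1), rss_e1, np.inf)
    if not fit_offset:
        return np.zeros_like(s0_e1), s0_e1, np.maximum(rss_e1, 0.0)

    # edge S0 = 0
    a_e2 = np.maximum(Sy / m, 0.0)
    rss_e2 = Syy - 2.0 * a_e2 * Sy + a_e2**2 * m

    # interior solution of the 2x2 normal equations
    det = m * See - Se**2
    with np.errstate(divide="ignore", invalid="ignore"):
        a_in = (See * Sy - Se * Sey) / det
        s0_in = (m * Sey - Se * Sy) / det
    feasible = (det > 0) & (a_in >= 0) & (s0_in >= 0) & np.isfinite(a_in) & np.isfinite(s0_in)
    a_in = np.where(feasible, a_in, 0.0)
    s0_in = np.where(feasible, s0_in, 0.0)
    with np.errstate(over="ignore", invalid="ignore"):
        rss_in = np.where(
            feasible,
            Syy - 2.0 * (a_in * Sy + s0_in * Sey)
            + a_in**2 * m + 2.0 * a_in * s0_in * Se + s0_in**2 * See,
            np.inf,
        )
    rss_in = np.where(np.isfinite(rss_in), rss_in, np.inf)

    use_in = feasible & (rss_in <= np.minimum(rss_e1, rss_e2))
    use_e1 = ~use_in & (rss_e1 <= rss_e2)
    A = np.where(use_in, a_in, np.where(use_e1, 0.0, a_e2))
    S0 = np.where(use_in, s0_in, np.where(use_e1, s0_e1, 0.0))
    rss = np.where(use_in, rss_in, np.where(use_e1, rss_e1, rss_e2))
    return A, S0, np.maximum(rss, 0.0)


def _profile_rss(y, te, T, sums, fit_offset):
    """Profile objective at per-voxel T values; returns (A, S0, RSS), each (n,)."""
    Sy, Syy = sums
    m = te.size
    T = np.asarray(T, dtype=float)
    e = np.exp(-te[None, :] / T[:, None])  # (n, m)
    Se = e.sum(axis=1)
    See = (e * e).sum(axis=1)
    Sey = (y * e).sum(axis=1)
    return _nnls2(Sy, Syy, Se, See, Sey, m, fit_offset)


def _fit_batch(y: np.ndarray, te: np.ndarray, opts: FitOptions):
    """Fit every row of ``y`` (n, m) against echo times ``te`` (m,).

    Returns arrays (A, S0, T, rss, converged) of length n.
    """
    n, m = y.shape
    lo, hi = opts.t_bounds
    finite = np.all(np.isfinite(y), axis=1) & np.any(y > 0, axis=1)
    y_safe = np.where(np.isfinite(y), y, 0.0)
    # normalize each voxel to unit peak: makes the fit exactly scale
    # equivariant (A, S0 scale with the signal; T is scale-free)
    scale = y_safe.max(axis=1)
    scale_safe = np.where(scale > 0, scale, 1.0)
    y_safe = y_safe / scale_safe[:, None]
    Sy = y_safe.sum(axis=1)
    Syy = (y_safe * y_safe).sum(axis=1)
    sums = (Sy, Syy)

    # profile scan over a log-spaced T grid shared by all voxels
    grid = np.geomspace(lo, hi, opts.grid_size)
    E = np.exp(-te[None, :] / grid[:, None])  # (G, m)
    _, _, rss_grid = _nnls2(
        Sy[:, None], Syy[:, None], E.sum(axis=1)[None, :], (E * E).sum(axis=1)[None, :],
        y_safe @ E.T, m, opts.fit_offset,
    )
    best = np.argmin(rss_grid, axis=1)

    # bracket the per-voxel minimum by the neighboring grid points
    t_lo = grid[np.maximum(best - 1, 0)]
    t_hi = grid[np.minimum(best + 1, grid.size - 1)]

    # golden-section refinement of the 1-D profile objective
    width0 = float(np.max(np.log(t_hi / np.maximum(t_lo, lo))))
    n_iter = int(np.ceil(np.log(opts.xtol / max(width0, opts.xtol)) / np.log(_GOLDEN))) + 2
    n_iter = min(max(n_iter, 1), opts.max_iter)
    a, b = t_lo.copy(), t_hi.copy()
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    _, _, fc = _profile_rss(y_safe, te, c, sums, opts.fit_offset)
    _, _, fd = _profile_rss(y_safe, te, d, sums, opts.fit_offset)
    for _ in range(n_iter):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_new = b - _GOLDEN * (b - a)
        d_new = a + _GOLDEN * (b - a)
        # only one of the two probes is new per voxel
        c, d = c_new, d_new
        _, _, fc = _profile_rss(y_safe, te, c, sums, opts.fit_offset)
        _, _, fd = _profile_rss(y_safe, te, d, sums, opts.fit_offset)
    T = 0.5 * (a + b)
    A, S0, _ = _profile_rss(y_safe, te, T, sums, opts.fit_offset)
    # report RSS from the residuals directly (cancellation-free)
    model = A[:, None] + S0[:, None] * np.exp(-te[None, :] / T[:, None])
    rss = ((y_safe - model) ** 2).sum(axis=1)
    # undo the per-voxel normalization
    A = A * scale_safe
    S0 = S0 * scale_safe
    rss = rss * scale_safe**2

    pinned = (T <= lo * (1.0 + 1e-6)) | (T >= hi * (1.0 - 1e-6))
    identifiable = S0 > 0
    converged = finite & identifiable & ~pinned
    A = np.where(converged, A, np.nan)
    S0 = np.where(converged, S0, np.nan)
    T = np.where(converged, T, np.nan)
    rss = np.where(finite, rss, np.nan)
    return A, S0, T, rss, converged


def fit_voxel(signal: np.ndarray, echo_times: np.ndarray, options: FitOptions | None = None) -> FitResult:
    """Fit the decay model to a single voxel's echo train.

    Raises on structurally invalid input (< 3 echoes, negative samples);
    numerically degenerate voxels (non-finite, flat, boundary-pinned)
    return ``converged=False`` rather than raising, so a single bad voxel
    never aborts a map.
    """
    y = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if y.ndim != 1 or te.ndim != 1 or y.size != te.size:
        raise ValueError("signal and echo_times must be 1-D and equally long")
    if y.size < 3:
        raise ValueError("at least 3 echoes required (model has 3 parameters)")
    if np.any(np.isfinite(y) & (y < 0)):
        raise ValueError("magnitude signal must be non-negative")
    opts = options or FitOptions()
    A, S0, T, rss, conv = _fit_batch(y[None, :], te, opts)
    return FitResult(
        params=DecayParams(A=float(A[0]), S0=float(S0[0]), T=float(T[0])),
        converged=bool(conv[0]),
        rss=float(rss[0]),
        n_echoes_used=int(y.size),
    )


@dataclass
class ParametricMap:
    """Per-voxel fitted parameters for one echo series.

    ``T_map`` is in ms with NaN at invalid voxels; ``valid_mask`` marks
    converged fits.  Spatial shape matches the source series.
    """

    T_map: np.ndarray
    A_map: np.ndarray
    S0_map: np.ndarray
    valid_mask: np.ndarray
    rss_map: np.ndarray
    protocol: Protocol

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.T_map.shape)


def fit_map(
    series: EchoSeries,
    options: FitOptions | None = None,
    mask: np.ndarray | None = None,
) -> ParametricMap:
    """Fit the decay model at every voxel of a series (optionally within a mask).

    Voxels outside ``mask`` — and voxels whose fit fails — are NaN in the
    parameter maps and False in ``valid_mask``.  Deterministic for fixed
    input.
    """
    opts = options or FitOptions()
    shape = series.spatial_shape
    if mask is None:
        mask = series.voxels.max(axis=3) > 0
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} != series spatial shape {shape}")

    T_map = np.full(shape, np.nan)
    A_map = np.full(shape, np.nan)
    S0_map = np.full(shape, np.nan)
    rss_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    idx = np.nonzero(mask)
    if idx[0].size:
        y = series.voxels[idx]  # (n, m)
        A, S0, T, rss, conv = _fit_batch(y, series.echo_times_ms, opts)
        T_map[idx] = T
        A_map[idx] = A
        S0_map[idx] = S0
        rss_map[idx] = rss
        valid[idx] = conv
    return ParametricMap(
        T_map=T_map, A_map=A_map, S0_map=S0_map, valid_mask=valid, rss_map=rss_map,
        protocol=series.protocol,
    )
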