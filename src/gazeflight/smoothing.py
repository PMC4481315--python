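"""Penalized least-squares (Whittaker) smoothing and derivative estimation.

The smoother minimizes

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^d z_i)^2

on a uniformly indexed series ``y``.  Missing samples (NaN) get weight zero
and are interpolated by the roughness penalty, which is how sparse
wingbeat-rate channels (shoulders, body yaw) are brought up to the full
camera rate.  Default penalty weights follow the grades used for the flight
recordings: coordinates lambda=100, head yaw lambda=5000, body yaw
lambda=1e6, each with an admissible leave-one-out cross-validation error
(0.5, 1 and 2 respectively, in units of the smoothed signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


@dataclass(frozen=True)
class SmootherSettings:
    """Penalty configuration for one channel grade.

    Parameters
    ----------
    lam:
        Roughness penalty weight, dimensionless, >= 0.
    difference_order:
        Order ``d`` of the penalized finite difference (1, 2 or 3).
    cve_bound:
        Maximum admissible leave-one-out cross-validation error in the
        units of the smoothed signal; ``None`` disables the check.
    """

    lam: float
    difference_order: int = 2
    cve_bound: float | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.difference_order not in (1, 2, 3):
            raise ValueError("difference_order must be 1, 2 or 3")


COORDINATE_SETTINGS = SmootherSettings(lam=100.0, cve_bound=0.5)
HEAD_YAW_SETTINGS = SmootherSettings(lam=5000.0, cve_bound=1.0)
BODY_YAW_SETTINGS = SmootherSettings(lam=1e6, cve_bound=2.0)


@dataclass(frozen=True)
class PipelineSmoothing:
    """Bundle of per-channel smoother grades used by the yaw pipeline."""

    coordinates: SmootherSettings = field(default_factory=lambda: COORDINATE_SETTINGS)
    head: SmootherSettings = field(default_factory=lambda: HEAD_YAW_SETTINGS)
    body: SmootherSettings = field(default_factory=lambda: BODY_YAW_SETTINGS)


DEFAULT_SMOOTHING = PipelineSmoothing()


def _difference_matrix(n: int, order: int) -> sp.csc_matrix:
    d = sp.eye(n, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    return d


def _weights_from_nan(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = np.isfinite(y).astype(float)
    y_filled = np.where(w > 0, y, 0.0)
    return w, y_filled


def whittaker_smooth(
    y: np.ndarray,
    settings: SmootherSettings,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth ``y`` by penalized least squares; NaNs are interpolated.

    Returns the smoothed series ``z`` on the full index.  ``weights``
    overrides the NaN-derived 0/1 weights (entries with weight 0 are
    interpolated).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("whittaker_smooth expects a 1-D series")
    n = y.size
    d = settings.difference_order
    if weights is None:
        w, y_filled = _weights_from_nan(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must match y in shape")
        w = np.where(np.isfinite(y), w, 0.0)
        y_filled = np.where(w > 0, y, 0.0)
    n_obs = int(np.count_nonzero(w))
    if n_obs == 0:
        raise ValueError("all samples missing; nothing to smooth")
    if n_obs < d + 1:
        raise ValueError(
            f"need at least difference_order+1={d + 1} observed points, got {n_obs}"
        )
    if settings.lam == 0:
        if n_obs < n:
            raise ValueError("lambda=0 cannot interpolate gaps")
        return y.copy()
    dmat = _difference_matrix(n, d)
    a = sp.diags(w) + settings.lam * (dmat.T @ dmat)
    z = splu(a.tocsc()).solve(w * y_filled)
    return z


def _hat_diagonal(n: int, w: np.ndarray, settings: SmootherSettings) -> np.ndarray:
    """Diagonal of the smoother (hat) matrix H = A^{-1} W."""
    dmat = _difference_matrix(n, settings.difference_order)
    a = (sp.diags(w) + settings.lam * (dmat.T @ dmat)).tocsc()
    lu = splu(a)
    diag = np.empty(n)
    chunk = 512
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rhs = np.zeros((n, stop - start))
        rhs[np.arange(start, stop), np.arange(stop - start)] = 1.0
        sol = lu.solve(rhs)
        diag[start:stop] = sol[np.arange(start, stop), np.arange(stop - start)]
    return diag * w


def _loo_residuals_lambda0(y: np.ndarray, order: int) -> np.ndarray:
    """Exact leave-one-out interpolation residuals in the lambda->0+ limit.

    With a vanishing penalty every retained point is reproduced exactly and
    the held-out value is filled by minimizing the d-th difference roughness
    with all neighbors pinned, which is a scalar quadratic problem.
    """
    n = y.size
    dmat = _difference_matrix(n, order).toarray()
    residuals = np.empty(n)
    for i in range(n):
        col = dmat[:, i]
        rows = col != 0
        z0 = y.copy()
        z0[i] = 0.0
        r0 = dmat[rows] @ z0
        c = col[rows]
        denom = float(c @ c)
        if denom == 0.0:  # point never enters the penalty; LOO undefined
            residuals[i] = np.nan
            continue
        z_i = -float(c @ r0) / denom
        residuals[i] = y[i] - z_i
    return residuals


def cross_validation_error(y: np.ndarray, settings: SmootherSettings) -> float:
    """Root-mean-square leave-one-out residual of the smoother.

    Computed from the hat-matrix diagonal (``r_i / (1 - h_ii)``); gap
    samples are excluded from the average.  At lambda=0 the identity fit
    makes the hat formula degenerate, so the exact penalty-interpolation
    limit is used instead.
    """
    y = np.asarray(y, dtype=float)
    w, _ = _weights_from_nan(y)
    observed = w > 0
    if not observed.any():
        raise ValueError("all samples missing")
    if settings.lam == 0:
        if not observed.all():
            raise ValueError("lambda=0 cannot interpolate gaps")
        res = _loo_residuals_lambda0(y, settings.difference_order)
        res = res[np.isfinite(res)]
        return float(np.sqrt(np.mean(res**2)))
    z = whittaker_smooth(y, settings)
    h = _hat_diagonal(y.size, w, settings)
    denom = 1.0 - h[observed]
    denom = np.where(denom < 1e-12, np.nan, denom)
    loo = (y[observed] - z[observed]) / denom
    loo = loo[np.isfinite(loo)]
    return float(np.sqrt(np.mean(loo**2)))


def derivative(z: np.ndarray, sample_rate: float) -> np.ndarray:
    """Time derivative by central differences (one-sided at the ends)."""
    z = np.asarray(z, dtype=float)
    if z.size < 3:
        raise ValueError("derivative needs at least 3 points")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    return np.gradient(z, 1.0 / sample_rate, edge_order=2)


def unwrap_degrees(phi: np.ndarray) -> np.ndarray:
    """Unwrap an angle series in degrees, ignoring NaN gaps."""
    phi = np.asarray(phi, dtype=float)
    out = phi.copy()
    obs = np.isfinite(phi)
    out[obs] = np.rad2deg(np.unwrap(np.deg2rad(phi[obs])))
    return out
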