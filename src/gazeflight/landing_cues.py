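"""Optical landing cues and the coefficient-of-variation parsimony analysis.

Approaching birds can initiate landing from several optical variables:
the azimuthal retinal extent of the perch alpha (difference of the two
perch-edge azimuths), its expansion speed Omega = d(alpha)/dt, the
relative retinal expansion velocity RREV = Omega/alpha and the
time-to-collision estimate tau = alpha/Omega.  Aligning trials at
landing initiation (the tail-pitch instant) and computing, per time
step, the across-trial coefficient of variation (SD/mean) of each
parameter identifies the most parsimonious landing cue: the parameter a
fixed-threshold trigger would hold most constant across trials.
The analysis window starts 85 ms before landing initiation (visuomotor
delay makes later samples unable to influence the trigger; the final
30 ms band is annotated, not excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import smoothing
from .smoothing import COORDINATE_SETTINGS, SmootherSettings
from .trial_io import ArenaGeometry, TrialRecording

CUE_PARAMETERS = ("alpha", "omega_exp", "rrev", "tau", "speed_abs", "speed_rel")
DEFAULT_WINDOW = (-0.085, 0.0)
VISUOMOTOR_BAND = (-0.030, 0.0)
#: |Omega| below this (deg/s) counts as zero expansion: tau is undefined
OMEGA_FLOOR = 1e-6


@dataclass
class LandingCueSeries:
    """Optical landing parameters for one trial, aligned at landing initiation."""

    trial_id: str
    sample_rate: float
    t_rel: np.ndarray  # s, negative before the tail-pitch instant
    alpha: np.ndarray  # deg
    omega_exp: np.ndarray  # deg/s
    rrev: np.ndarray  # 1/s
    tau: np.ndarray  # s (NaN where Omega = 0)
    speed_abs: np.ndarray  # m/s
    speed_rel: np.ndarray  # m/s relative to the moving perch

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_rel": self.t_rel, "alpha": self.alpha, "omega_exp": self.omega_exp,
            "rrev": self.rrev, "tau": self.tau,
            "speed_abs": self.speed_abs, "speed_rel": self.speed_rel,
        })


@dataclass
class CvTable:
    """Per-time-step coefficient of variation for each landing parameter."""

    t_rel: np.ndarray
    cv: pd.DataFrame  # one column per parameter, indexed like t_rel
    window: tuple[float, float]
    window_mean_cv: pd.Series
    most_parsimonious: str
    visuomotor_band: tuple[float, float] = VISUOMOTOR_BAND
    n_trials: int = 0


def _expansion_ratios(alpha: np.ndarray, omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RREV = Omega/alpha and tau = alpha/Omega (tau masked at ~zero Omega)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rrev = np.where(alpha > 0, omega / alpha, np.nan)
        nonzero = np.abs(omega) > OMEGA_FLOOR
        tau = np.where(nonzero, alpha / np.where(nonzero, omega, 1.0), np.nan)
    return rrev, tau


def _perch_edges(
    rec: TrialRecording, geometry: ArenaGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = rec.n_frames
    if rec.perch_track is not None:
        center = rec.perch_track
    else:
        center = np.broadcast_to(np.asarray(geometry.perch_center), (n, 2))
    half_w = geometry.perch_width / 2.0
    left = center + np.array([0.0, -half_w])
    right = center + np.array([0.0, half_w])
    return center, left, right


def landing_cue_series(
    rec: TrialRecording,
    geometry: ArenaGeometry,
    alpha_smoothing: SmootherSettings | None = COORDINATE_SETTINGS,
    coordinate_smoothing: SmootherSettings = COORDINATE_SETTINGS,
) -> LandingCueSeries:
    """Compute alpha, Omega, RREV, tau and speeds for one trial.

    alpha comes from the difference of the perch-edge azimuths (moving
    perch when tracked, rest position otherwise) and is smoothed with
    the coordinate-grade settings before differentiation (pass
    ``alpha_smoothing=None`` to differentiate raw).  tau is masked where
    Omega vanishes; tau * RREV = 1 wherever both are defined.
    """
    if rec.landing_init_time is None:
        raise ValueError(f"trial {rec.trial_id}: landing_init_time missing")
    fs = rec.sample_rate
    head = np.column_stack([
        smoothing.whittaker_smooth(rec.head_center[:, 0], coordinate_smoothing),
        smoothing.whittaker_smooth(rec.head_center[:, 1], coordinate_smoothing),
    ])
    center, left, right = _perch_edges(rec, geometry)

    def azimuthal_extent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        va, vb = a - head, b - head
        ang = np.rad2deg(np.arctan2(va[:, 1], va[:, 0]) - np.arctan2(vb[:, 1], vb[:, 0]))
        return np.abs((ang + 180.0) % 360.0 - 180.0)

    alpha = azimuthal_extent(left, right)
    if alpha_smoothing is not None:
        alpha = smoothing.whittaker_smooth(alpha, alpha_smoothing)
    omega = smoothing.derivative(alpha, fs)
    rrev, tau = _expansion_ratios(alpha, omega)

    vx = smoothing.derivative(head[:, 0], fs)
    vy = smoothing.derivative(head[:, 1], fs)
    speed_abs = np.hypot(vx, vy)
    rel = head - center
    speed_rel = np.hypot(smoothing.derivative(rel[:, 0], fs),
                         smoothing.derivative(rel[:, 1], fs))

    return LandingCueSeries(
        trial_id=rec.trial_id,
        sample_rate=fs,
        t_rel=rec.t - rec.landing_init_time,
        alpha=alpha, omega_exp=omega, rrev=rrev, tau=tau,
        speed_abs=speed_abs, speed_rel=speed_rel,
    )


def _common_grid(cohort: list[LandingCueSeries], window: tuple[float, float],
                 rate: float | None = None) -> np.ndarray:
    fs = rate if rate is not None else min(s.sample_rate for s in cohort)
    start = max(window[0], max(s.t_rel[0] for s in cohort))
    stop = min(window[1], min(s.t_rel[-1] for s in cohort))
    if stop <= start:
        raise ValueError("trials do not overlap inside the analysis window")
    n = int(np.floor((stop - start) * fs)) + 1
    return stop - np.arange(n)[::-1] / fs


def cv_analysis(
    cohort: list[LandingCueSeries],
    window: tuple[float, float] = DEFAULT_WINDOW,
    parameters: tuple[str, ...] = CUE_PARAMETERS,
    mean_floor: float = 1e-9,
) -> CvTable:
    """Across-trial coefficient of variation per parameter and time step.

    Trials are linearly resampled onto a common relative-time grid.  The
    winner is the parameter with the lowest mean c.v. over the window
    (steps where a parameter's across-trial mean is ~0 are masked).
    """
    if len(cohort) < 3:
        raise ValueError("cv analysis needs at least 3 trials")
    grid = _common_grid(cohort, window)
    cv = {}
    for name in parameters:
        stack = np.stack([
            np.interp(grid, s.t_rel, getattr(s, name)) for s in cohort
        ])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(np.abs(mean) > mean_floor, sd / np.abs(mean), np.nan)
        c = np.where(np.isnan(stack).any(axis=0), np.nan, c)
        cv[name] = c
    table = pd.DataFrame(cv, index=grid)
    window_mean = table.mean(axis=0, skipna=False)
    defined = window_mean.dropna()
    if defined.empty:
        raise ValueError("no parameter has a defined c.v. over the whole window")
    return CvTable(
        t_rel=grid, cv=table, window=window,
        window_mean_cv=window_mean,
        most_parsimonious=str(defined.idxmin()),
        n_trials=len(cohort),
    )


def _decimate_series(series: LandingCueSeries, factor: int) -> LandingCueSeries:
    """Rebuild derivative-based cues after decimating alpha."""
    # anchor the decimation at the landing-initiation sample
    zero = int(np.argmin(np.abs(series.t_rel)))
    idx = np.arange(zero % factor, series.t_rel.size, factor)
    fs = series.sample_rate / factor
    t_rel = series.t_rel[idx]
    alpha = series.alpha[idx]
    omega = smoothing.derivative(alpha, fs)
    rrev, tau = _expansion_ratios(alpha, omega)
    return LandingCueSeries(
        trial_id=series.trial_id, sample_rate=fs, t_rel=t_rel,
        alpha=alpha, omega_exp=omega, rrev=rrev, tau=tau,
        speed_abs=series.speed_abs[idx], speed_rel=series.speed_rel[idx],
    )


def downsample_check(
    cohort: list[LandingCueSeries],
    rate: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    parameters: tuple[str, ...] = CUE_PARAMETERS,
) -> tuple[CvTable, float]:
    """Repeat the c.v. analysis at a reduced sampling rate.

    alpha is decimated before differentiation (as when acquiring at the
    lower rate).  Returns the reduced-rate table and the Spearman rank
    correlation of the parameter ordering against the full-rate analysis.
    """
    full_rate = cohort[0].sample_rate
    if rate > full_rate:
        raise ValueError("target rate exceeds the original rate")
    factor = int(round(full_rate / rate))
    if abs(full_rate / rate - factor) > 1e-9:
        raise ValueError("target rate must divide the original rate")
    if factor == 1:
        table = cv_analysis(cohort, window=window, parameters=parameters)
        return table, 1.0
    reduced = [_decimate_series(s, factor) for s in cohort]
    table_full = cv_analysis(cohort, window=window, parameters=parameters)
    table_low = cv_analysis(reduced, window=window, parameters=parameters)
    a = table_full.window_mean_cv[list(parameters)]
    b = table_low.window_mean_cv[list(parameters)]
    ok = a.notna() & b.notna()
    rho = float(stats.spearmanr(a[ok], b[ok]).statistic)
    return table_low, rho
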