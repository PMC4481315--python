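"""Head-saccade detection and statistics.

A head saccade is a maximal run of samples where the absolute head yaw
velocity exceeds 400 deg/s for at least 12 ms (24 samples at 2000 Hz).
Event boundaries are then extended outward to the nearest sample where
|omega| drops below a 100 deg/s floor or reaches a local minimum,
whichever comes first within 10 ms, so the reported amplitude captures
the full head turn rather than only its supra-threshold core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import YawTraces

OMEGA_THRESHOLD = 400.0  # deg/s
MIN_DURATION_MS = 12.0
BOUNDARY_FLOOR = 100.0  # deg/s
MAX_EXTENSION_MS = 10.0


@dataclass
class SaccadeEvent:
    """One detected head saccade.

    ``start``/``end`` are the amplitude (extended) boundaries;
    ``thresh_start``/``thresh_end`` the supra-threshold crossings that
    define the detection duration.  Amplitudes are signed (positive =
    leftward); summaries take magnitudes.
    """

    start: float
    end: float
    thresh_start: float
    thresh_end: float
    duration_ms: float  # supra-threshold duration
    direction: str  # "left" | "right"
    amplitude_absolute: float  # deg, head yaw change, arena frame
    amplitude_relative: float  # deg, head-minus-body change
    peak_velocity: float  # deg/s
    mean_velocity: float  # deg/s over the extended boundaries
    flight_phase: str | None = None
    stroke_at_start: tuple[str, float] | None = None  # (stroke, percent 0-100)
    stroke_at_end: tuple[str, float] | None = None


def _supra_runs(omega: np.ndarray, threshold: float, min_samples: int) -> list[tuple[int, int]]:
    above = np.abs(omega) > threshold  # strict: equality does not count
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_samples]


def _extend(omega_abs: np.ndarray, idx: int, step: int, limit: int, floor: float) -> int:
    """Walk outward from a threshold crossing to the amplitude boundary."""
    n = len(omega_abs)
    pos = idx
    for _ in range(limit):
        nxt = pos + step
        if nxt < 0 or nxt >= n:
            break
        if omega_abs[nxt] < floor:
            return nxt
        if omega_abs[nxt] > omega_abs[pos]:  # passed a local minimum
            return pos
        pos = nxt
    return pos


def detect_saccades(
    yaw: YawTraces,
    omega_threshold: float = OMEGA_THRESHOLD,
    min_duration_ms: float = MIN_DURATION_MS,
    boundary_floor: float = BOUNDARY_FLOOR,
    max_extension_ms: float = MAX_EXTENSION_MS,
) -> list[SaccadeEvent]:
    """Detect head saccades on the smoothed yaw-rate trace."""
    t = yaw.t
    dt = np.diff(t)
    if dt.size and (np.max(dt) > 1.01 * np.min(dt)):
        raise ValueError("saccade detection requires uniform sampling")
    fs = yaw.sample_rate
    omega = np.asarray(yaw.omega_head, dtype=float)
    min_samples = int(round(min_duration_ms / 1000.0 * fs))
    runs = _supra_runs(omega, omega_threshold, min_samples)
    omega_abs = np.abs(omega)
    limit = int(round(max_extension_ms / 1000.0 * fs))

    events: list[SaccadeEvent] = []
    for k, (s, e) in enumerate(runs):
        ext_s = _extend(omega_abs, s, -1, limit, boundary_floor)
        ext_e = _extend(omega_abs, e - 1, +1, limit, boundary_floor)
        if events and ext_s <= int(round(events[-1].end * fs)):
            ext_s = s  # do not let extensions merge into the previous event
        amp_abs = float(yaw.phi_head[ext_e] - yaw.phi_head[ext_s])
        amp_rel = float(yaw.phi_diff[ext_e] - yaw.phi_diff[ext_s])
        span = float(t[ext_e] - t[ext_s])
        events.append(SaccadeEvent(
            start=float(t[ext_s]),
            end=float(t[ext_e]),
            thresh_start=float(t[s]),
            thresh_end=float(t[e - 1]),
            duration_ms=(e - s) / fs * 1000.0,
            direction="left" if np.mean(omega[s:e]) > 0 else "right",
            amplitude_absolute=amp_abs,
            amplitude_relative=amp_rel,
            peak_velocity=float(np.max(omega_abs[s:e])),
            mean_velocity=abs(amp_abs) / span if span > 0 else np.nan,
        ))
    return events


def events_frame(events: list[SaccadeEvent], flight: str | None = None,
                 bird: str | None = None) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "flight": flight, "bird": bird, "start": ev.start, "end": ev.end,
            "duration_ms": ev.duration_ms,
            "duration_full_ms": (ev.end - ev.start) * 1000.0,
            "direction": ev.direction,
            "amplitude_absolute": ev.amplitude_absolute,
            "amplitude_relative": ev.amplitude_relative,
            "peak_velocity": ev.peak_velocity, "mean_velocity": ev.mean_velocity,
            "flight_phase": ev.flight_phase,
        })
    return pd.DataFrame(rows)


_STAT_COLUMNS = ("amplitude_absolute", "amplitude_relative", "duration_ms",
                 "peak_velocity", "mean_velocity")


def saccade_statistics(events: pd.DataFrame, per: str = "cohort",
                       stat: str = "median") -> pd.DataFrame:
    """Summaries aggregated flight -> bird -> cohort, never pooled raw.

    ``per`` selects the aggregation depth: "flight", "bird" or "cohort".
    Amplitudes enter as magnitudes.  The chosen ``stat`` (median or mean)
    is applied within each flight; bird and cohort levels average the
    lower level, following the per-bird-first convention.
    """
    if events.empty:
        warnings.warn("no saccade events to summarize")
        return pd.DataFrame()
    data = events.copy()
    for col in ("amplitude_absolute", "amplitude_relative"):
        data[col] = data[col].abs()
    agg = getattr(data.groupby(["bird", "flight"])[list(_STAT_COLUMNS)], stat)()
    if per == "flight":
        return agg.reset_index()
    per_bird = agg.groupby(level="bird").mean()
    if per == "bird":
        return per_bird.reset_index()
    if per == "cohort":
        return per_bird.mean().to_frame().T
    raise ValueError(f"unknown aggregation level {per!r}")


def intersaccade_statistics(yaw: YawTraces, events: list[SaccadeEvent]) -> pd.DataFrame:
    """Absolute and body-relative yaw-rate statistics between saccades."""
    mask = np.ones(yaw.t.size, dtype=bool)
    for ev in events:
        mask &= ~((yaw.t >= ev.start) & (yaw.t <= ev.end))
    if not mask.any():
        warnings.warn("no intersaccadic samples")
        return pd.DataFrame()
    omega_abs = np.abs(yaw.omega_head[mask])
    dt = 1.0 / yaw.sample_rate
    omega_rel = np.abs(np.gradient(yaw.phi_diff, dt))[mask]
    return pd.DataFrame({
        "quantity": ["omega_absolute", "omega_relative"],
        "median": [float(np.median(omega_abs)), float(np.median(omega_rel))],
        "mean": [float(np.mean(omega_abs)), float(np.mean(omega_rel))],
        "n_samples": [int(mask.sum())] * 2,
    })


def amplitude_duration_regression(events: pd.DataFrame) -> dict:
    """OLS of |amplitude| (deg) on saccade duration (ms).

    Uses the onset-to-offset (extended boundary) duration when available
    — the quantity whose slope estimates the preferred head angular speed
    — and falls back to the supra-threshold duration.  Returns slope in
    deg/s (slope per ms x 1000), intercept (deg), Pearson r and R^2.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events for the regression")
    col = "duration_full_ms" if "duration_full_ms" in events.columns else "duration_ms"
    x = events[col].to_numpy(dtype=float)
    y = events["amplitude_absolute"].abs().to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all durations equal")
    fit = stats.linregress(x, y)
    return {
        "slope_deg_per_s": fit.slope * 1000.0,
        "intercept_deg": fit.intercept,
        "r": fit.rvalue,
        "r_squared": fit.rvalue**2,
    }


def saccadic_fraction(
    yaw: YawTraces,
    events: list[SaccadeEvent],
    turn_window: tuple[float, float],
) -> tuple[float, pd.DataFrame]:
    """Percent of the total head reorientation carried by saccades.

    Returns the percentage and the cumulative saccadic-amplitude curve
    (fraction of the total turn amplitude vs time).
    """
    t0, t1 = turn_window
    sel = (yaw.t >= t0) & (yaw.t <= t1)
    if not sel.any():
        raise ValueError("empty turn window")
    total = float(yaw.phi_head[sel][-1] - yaw.phi_head[sel][0])
    if abs(total) < 1e-9:
        raise ValueError("zero net reorientation over the turn window; fraction undefined")
    in_window = [ev for ev in events if t0 <= ev.start and ev.end <= t1]
    sacc_sum = sum(abs(ev.amplitude_absolute) for ev in in_window)
    percent = 100.0 * sacc_sum / abs(total)
    times = sorted(ev.end for ev in in_window)
    cum = np.cumsum([abs(ev.amplitude_absolute) for ev in
                     sorted(in_window, key=lambda e: e.end)])
    curve = pd.DataFrame({
        "t": times,
        "cumulative_fraction": cum / abs(total) if len(cum) else cum,
    })
    return percent, curve


def _stroke_phase(time: float, beats: pd.DataFrame) -> tuple[str, float] | None:
    for _, b in beats.iterrows():
        if b["down_start"] <= time < b["down_end"]:
            frac = 100.0 * (time - b["down_start"]) / (b["down_end"] - b["down_start"])
            return "down", frac
        if b["down_end"] <= time < b["up_end"]:
            frac = 100.0 * (time - b["down_end"]) / (b["up_end"] - b["down_end"])
            return "up", frac
    return None


def stroke_phase_of_saccades(
    events: pd.DataFrame,
    beats_by_flight: dict[str, pd.DataFrame],
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Where in the stroke cycle saccades start and end.

    For each event boundary the containing stroke (down/up) and the
    percent elapsed within it are histogrammed in 10% bins, normalized
    per bird (start and end counts each sum to 1 over the down+up pair)
    and averaged across birds.
    """
    if bins is None:
        bins = np.arange(0.0, 101.0, 10.0)
    assignments = []
    unassigned = 0
    for _, ev in events.iterrows():
        beats = beats_by_flight.get(ev["flight"])
        for edge, col in (("start", "start"), ("end", "end")):
            placed = None if beats is None else _stroke_phase(ev[col], beats)
            if placed is None:
                unassigned += 1
                continue
            stroke, frac = placed
            assignments.append({"bird": ev["bird"], "edge": edge,
                                "stroke": stroke, "percent": frac})
    if unassigned:
        warnings.warn(f"{unassigned} saccade boundaries outside annotated wingbeats")
    if not assignments:
        return pd.DataFrame()
    table = pd.DataFrame(assignments)
    per_bird = []
    for bird, grp in table.groupby("bird"):
        for edge, egrp in grp.groupby("edge"):
            total = len(egrp)
            for stroke in ("down", "up"):
                vals = egrp.loc[egrp["stroke"] == stroke, "percent"].to_numpy()
                counts, _ = np.histogram(vals, bins=bins)
                for left, c in zip(bins[:-1], counts):
                    per_bird.append({"bird": bird, "edge": edge, "stroke": stroke,
                                     "bin_left": left, "density": c / total})
    frame = pd.DataFrame(per_bird)
    return (frame.groupby(["edge", "stroke", "bin_left"])["density"]
            .mean().reset_index())
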