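"""Yaw traces, wingbeat records, advance ratio and U-turn segmentation.

Head yaw is the planform arctangent of the anterior-posterior head-marker
vector; body yaw is the forward normal of the shoulder-to-shoulder vector,
observed only at the four stroke instants per wingbeat and interpolated to
the full camera rate by the body-grade Whittaker smoother.  Yaw 0 degrees
faces away from the perch along the long arena axis; positive yaw is a
leftward (counter-clockwise from above) rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import smoothing
from .smoothing import DEFAULT_SMOOTHING, PipelineSmoothing
from .trial_io import TrialRecording


class KinematicsError(ValueError):
    pass


@dataclass
class YawTraces:
    """Filtered head/body yaw and derived rates at the full sample rate."""

    t: np.ndarray
    sample_rate: float
    phi_head: np.ndarray  # deg, unwrapped, smoothed
    phi_body: np.ndarray  # deg, unwrapped, smoothed + gap-interpolated
    phi_diff: np.ndarray  # deg, head - body
    omega_head: np.ndarray  # deg/s
    speed: np.ndarray  # m/s, planform head speed
    head_xy: np.ndarray  # smoothed planform head center, m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "phi_head": self.phi_head, "phi_body": self.phi_body,
            "phi_diff": self.phi_diff, "omega_head": self.omega_head,
            "speed": self.speed,
        })


def _planform_angle(vec_xy: np.ndarray, channel: str) -> np.ndarray:
    norms = np.hypot(vec_xy[:, 0], vec_xy[:, 1])
    observed = np.isfinite(norms)
    bad = observed & (norms < 1e-9)
    if bad.any():
        frame = int(np.argmax(bad))
        raise KinematicsError(f"coincident {channel} marker pair at frame {frame}")
    ang = np.full(vec_xy.shape[0], np.nan)
    ang[observed] = np.rad2deg(np.arctan2(vec_xy[observed, 1], vec_xy[observed, 0]))
    return ang


def compute_yaw(
    rec: TrialRecording,
    settings: PipelineSmoothing = DEFAULT_SMOOTHING,
) -> YawTraces:
    """Derive smoothed head/body yaw, yaw rate and flight speed."""
    head_vec = (rec.head_a - rec.head_b)[:, :2]
    phi_head_raw = smoothing.unwrap_degrees(_planform_angle(head_vec, "head"))
    phi_head = smoothing.whittaker_smooth(phi_head_raw, settings.head)

    shoulder_vec = (rec.shoulder_l - rec.shoulder_r)[:, :2]
    # forward body axis = shoulder left-right vector rotated -90 degrees
    phi_body_raw = smoothing.unwrap_degrees(
        _planform_angle(shoulder_vec, "shoulder") - 90.0
    )
    phi_body = smoothing.whittaker_smooth(phi_body_raw, settings.body)

    head_xy = np.column_stack([
        smoothing.whittaker_smooth(rec.head_center[:, 0], settings.coordinates),
        smoothing.whittaker_smooth(rec.head_center[:, 1], settings.coordinates),
    ])
    vx = smoothing.derivative(head_xy[:, 0], rec.sample_rate)
    vy = smoothing.derivative(head_xy[:, 1], rec.sample_rate)

    return YawTraces(
        t=rec.t,
        sample_rate=rec.sample_rate,
        phi_head=phi_head,
        phi_body=phi_body,
        phi_diff=phi_head - phi_body,
        omega_head=smoothing.derivative(phi_head, rec.sample_rate),
        speed=np.hypot(vx, vy),
        head_xy=head_xy,
    )


def advance_ratio(v: float, amplitude: float, frequency: float, wing_length: float) -> float:
    """Advance ratio J = V / (2 A f R).

    ``v`` is the wingbeat-averaged flight speed (m/s), ``amplitude`` the
    stroke angle between the most dorsal and most ventral wingtip position
    (rad), ``frequency`` the wingbeat frequency (Hz) and ``wing_length``
    the root-to-tip wing length (m).  Small J indicates hovering-like
    flight.
    """
    if amplitude <= 0 or frequency <= 0 or wing_length <= 0:
        raise KinematicsError("amplitude, frequency and wing length must be positive")
    return v / (2.0 * amplitude * frequency * wing_length)


def _beats_from_marks(rec: TrialRecording) -> list[dict]:
    """Group the stroke-mark stream into complete wingbeats."""
    marks = rec.stroke_marks
    beats = []
    i = 0
    while i < len(marks):
        if marks[i][1] != "down_start":
            i += 1
            continue
        if i + 4 < len(marks) and [m[1] for m in marks[i + 1:i + 5]] == [
            "down_mid", "down_end", "up_mid", "down_start"
        ]:
            ds, dm, de, um = (marks[i + k][0] for k in range(4))
            ue = marks[i + 4][0]
            beats.append({"down_start": ds, "down_mid": dm, "down_end": de,
                          "up_mid": um, "up_end": ue})
        i += 4
    return beats


def _wingtip_elevation(rec: TrialRecording, idx: np.ndarray, side: str) -> np.ndarray:
    tip = getattr(rec, f"wingtip_{side}")[idx]
    sh = getattr(rec, f"shoulder_{side}")[idx]
    planar = np.hypot(tip[:, 0] - sh[:, 0], tip[:, 1] - sh[:, 1])
    return np.arctan2(tip[:, 2] - sh[:, 2], planar)


def wingbeat_records(
    rec: TrialRecording,
    yaw: YawTraces | None = None,
    wing_length: float | None = None,
) -> pd.DataFrame:
    """One row per complete wingbeat: timing, frequency, down/up ratio,
    stroke amplitude, mean flight speed and (if ``wing_length``) advance
    ratio.  Phase labels are attached by :func:`segment_turn`."""
    beats = _beats_from_marks(rec)
    if not beats:
        return pd.DataFrame()
    rows = []
    for k, b in enumerate(beats):
        freq = 1.0 / (b["up_end"] - b["down_start"])
        du = (b["down_end"] - b["down_start"]) / (b["up_end"] - b["down_end"])
        row = {"index": k, **b, "frequency": freq, "du_ratio": du}
        sel = (rec.t >= b["down_start"]) & (rec.t < b["up_end"])
        if yaw is not None:
            row["mean_speed"] = float(np.mean(yaw.speed[sel]))
        idx = np.flatnonzero(sel & np.isfinite(rec.wingtip_l[:, 0]))
        amps = []
        for side in ("l", "r"):
            cols = np.flatnonzero(sel & np.isfinite(getattr(rec, f"wingtip_{side}")[:, 0]))
            if cols.size >= 2:
                elev = _wingtip_elevation(rec, cols, side)
                amps.append(float(np.max(elev) - np.min(elev)))
        row["amplitude"] = float(np.mean(amps)) if amps else np.nan
        del idx
        if wing_length is not None and amps and yaw is not None:
            row["advance_ratio"] = advance_ratio(
                row["mean_speed"], row["amplitude"], freq, wing_length
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _circular_mean_deg(angles: np.ndarray) -> float:
    rad = np.deg2rad(angles)
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def _wrap180(a: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


@dataclass
class TurnSegmentation:
    turn_start: float | None  # s, None when no turn found
    turn_end: float | None
    phase_labels: list[str]  # one per wingbeat
    n_turns: int


def segment_turn(rec: TrialRecording, deflection_threshold: float = 20.0) -> TurnSegmentation:
    """Split the flight into before/during/after-turn wingbeat phases.

    Mid-stroke (down_mid) wingtip planform positions define one point per
    beat; the heading of segments between consecutive points is compared
    with the pre-turn running heading (circular mean of the first three
    segments).  The turn starts at the first segment deviating by more
    than ``deflection_threshold`` degrees and ends at the first later
    segment pair whose headings re-align within the threshold.
    """
    beats = _beats_from_marks(rec)
    if len(beats) < 5:
        raise KinematicsError("need at least 5 wingbeats with mid-stroke positions")
    pts = []
    for b in beats:
        idx = int(np.argmin(np.abs(rec.t - b["down_mid"])))
        tips = np.array([rec.wingtip_l[idx, :2], rec.wingtip_r[idx, :2]])
        if not np.isfinite(tips).all():
            raise KinematicsError(f"missing mid-stroke wingtip at beat t={b['down_mid']}")
        pts.append(tips.mean(axis=0))
    pts_arr = np.asarray(pts)
    seg = np.diff(pts_arr, axis=0)
    headings = np.rad2deg(np.arctan2(seg[:, 1], seg[:, 0]))
    base = _circular_mean_deg(headings[:3])
    dev = np.abs(_wrap180(headings - base))

    n_beats = len(beats)
    start_seg = None
    for k in range(len(headings)):
        if dev[k] > deflection_threshold:
            start_seg = k
            break
    if start_seg is None:
        warnings.warn("no turn deflection found; whole trial labeled before_turn")
        return TurnSegmentation(None, None, ["before_turn"] * n_beats, 0)
    # walk back over the incipient deflection: the supra-threshold segment is
    # reached one or two beats after the wingtip trace first bends away
    supra_seg = start_seg
    onset_floor = deflection_threshold / 5.0
    while start_seg > 0:
        if dev[start_seg - 1] >= onset_floor:
            start_seg -= 1
        elif start_seg > 1 and dev[start_seg - 2] >= onset_floor:
            # tolerate a single quiet segment: body rotation can transiently
            # cancel the lateral chord displacement early in the turn
            start_seg -= 2
        else:
            break

    # the turn ends at the first segment pair (past the developed turn) whose
    # headings re-align within the threshold
    end_seg = len(headings) - 1
    for k in range(supra_seg + 1, len(headings)):
        if abs(_wrap180(headings[k] - headings[k - 1])) < deflection_threshold:
            end_seg = k
            break

    # a second deflection bout after re-alignment violates the single-U-turn
    # inclusion criterion
    n_turns = 1
    post = headings[end_seg:]
    if post.size >= 2:
        post_dev = np.abs(_wrap180(np.diff(post)))
        if np.any(post_dev > deflection_threshold):
            n_turns = 2
            warnings.warn("multiple turn episodes detected; single-U-turn assumption violated")

    turn_start = beats[start_seg]["down_mid"]
    turn_end = beats[min(end_seg, n_beats - 1)]["down_mid"]
    labels = []
    for k in range(n_beats):
        if k < start_seg:
            labels.append("before_turn")
        elif k <= end_seg:
            labels.append("during_turn")
        else:
            labels.append("after_turn")
    return TurnSegmentation(turn_start, turn_end, labels, n_turns)


@dataclass
class FlightFilterResult:
    passed: bool
    verdicts: dict[str, bool]
    reasons: list[str]


def flight_filters(
    rec: TrialRecording,
    yaw: YawTraces | None = None,
    segmentation: TurnSegmentation | None = None,
    max_altitude_change: float = 0.21,
    heading_tolerance: float = 45.0,
) -> FlightFilterResult:
    """Evaluate the kinematic trial-inclusion criteria.

    Implemented: a single complete U-turn, altitude range below 21 cm and
    a pre-takeoff heading within +-45 degrees of the initial flight
    direction.  Camera-coverage, first-attempt-landing and mesh-occlusion
    criteria are video-level and cannot be evaluated on kinematic input.
    """
    verdicts: dict[str, bool] = {}
    reasons: list[str] = []

    if segmentation is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segmentation = segment_turn(rec)
    verdicts["single_u_turn"] = segmentation.n_turns == 1
    if not verdicts["single_u_turn"]:
        reasons.append(f"expected one U-turn, found {segmentation.n_turns}")

    altitude_range = float(np.ptp(rec.head_center[:, 2]))
    verdicts["altitude_change"] = altitude_range < max_altitude_change
    if not verdicts["altitude_change"]:
        reasons.append(f"altitude change {altitude_range:.3f} m exceeds {max_altitude_change} m")

    if yaw is None:
        yaw = compute_yaw(rec)
    # initial flight direction from the first ~100 ms of head travel
    n0 = max(3, int(0.1 * rec.sample_rate))
    disp = yaw.head_xy[min(n0, len(rec.t) - 1)] - yaw.head_xy[0]
    flight_dir = np.rad2deg(np.arctan2(disp[1], disp[0]))
    mismatch = abs(float(_wrap180(yaw.phi_head[0] - flight_dir)))
    verdicts["takeoff_heading"] = mismatch <= heading_tolerance
    if not verdicts["takeoff_heading"]:
        reasons.append(
            f"takeoff heading off flight direction by {mismatch:.1f} deg (> {heading_tolerance})"
        )

    return FlightFilterResult(all(verdicts.values()), verdicts, reasons)
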