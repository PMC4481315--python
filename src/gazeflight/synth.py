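"""Synthetic U-turn trial generator with exact ground truth.

Every downstream stage (smoothing, yaw computation, saccade detection,
wingbeat-mode classification, gaze-feature histograms, landing-cue
analysis) is tested against trials built here, because the original
high-speed videos deposit no kinematic data.  The generator emulates the
study conditions:

* a 0.6 m x 1 m arena with a swinging perch (fore-aft excursion ~10 cm,
  sideways ~1 cm) near one end wall;
* a left U-turn "on a dime": straight out at ~1.05 m/s, a slower
  (~0.5 m/s) 180-degree turn, straight return at ~1.0 m/s with a final
  deceleration toward the perch;
* 2000 Hz head-marker traces whose planform arctangent reproduces the
  head yaw exactly before noise;
* saccadic head yaw: a staircase of raised-cosine velocity bumps timed at
  75% of the downstroke of turn-phase wingbeats, amplitudes scaled to the
  turn angle so the head is rotationally stabilized between saccades,
  with durations following the amplitude-duration regression
  (duration_ms = (amplitude + 14) / 1.5, i.e. a 1500 deg/s average);
* smooth body yaw following the flight-path tangent, observable only at
  the four stroke instants per wingbeat (as the shoulders were tracked);
* an intermittent wingbeat: ~17 Hz / downstroke-upstroke ratio ~1.35
  "normal" beats mixed with ~9.5 Hz / ratio ~0.53 "intermittent" beats;
* i.i.d. Gaussian tracking noise on marker positions with a 3-D RMS of
  1.3 mm;
* landing initiation defined as the instant the azimuthal retinal extent
  of the perch first exceeds a configured threshold, which makes the
  retinal perch size the cue that actually triggers landing in the
  synthetic cohort.

The raised-cosine saccade profile gives analytic amplitude, peak
velocity (2*amplitude/duration) and supra-threshold span, so recovery
tests never depend on the detector they examine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .trial_io import ArenaGeometry, TrialRecording

DEG = 180.0 / np.pi


class ConfigError(ValueError):
    """Synthetic trial configuration is infeasible."""


@dataclass(frozen=True)
class SaccadePlan:
    """One injected saccade: start time (s), signed amplitude (deg), duration (s)."""

    start: float
    amplitude: float
    duration: float

    @property
    def peak_velocity(self) -> float:
        """Analytic peak of the raised-cosine velocity bump, deg/s."""
        return 2.0 * abs(self.amplitude) / self.duration

    def supra_threshold_span(self, threshold: float) -> float:
        """Seconds during which |velocity| exceeds ``threshold``."""
        peak = self.peak_velocity
        if peak <= threshold:
            return 0.0
        q = 1.0 - 2.0 * threshold / peak
        return self.duration * (1.0 - np.arccos(q) / np.pi)

    def detectable(self, threshold: float = 400.0, min_duration_ms: float = 12.0) -> bool:
        return (
            self.peak_velocity > threshold
            and self.supra_threshold_span(threshold) >= min_duration_ms / 1000.0
        )


@dataclass(frozen=True)
class WingbeatPlan:
    mode: str  # "normal" | "intermittent"
    frequency: float  # Hz
    du_ratio: float  # downstroke period / upstroke period


@dataclass
class SyntheticTrialConfig:
    """Study-condition parameters for one synthetic trial."""

    seed: int = 0
    duration: float = 1.7
    sample_rate: float = 2000.0
    turn_direction: str = "left"

    # flight path (m, s, m/s); duration is a maximum — the trial ends when
    # the bird arrives at the perch approach point
    start_x: float = 0.18
    start_y: float = 0.24
    out_leg_length: float = 0.58
    out_speed: float = 1.05
    turn_speed: float = 0.51
    return_speed: float = 1.03
    final_speed: float = 0.6  # approach speeds stay near 1 m/s until shortly before touchdown
    turn_duration: float = 0.35
    speed_blend: float = 0.10
    approach_taper_distance: float = 0.30  # decelerate inside this range to the aim point
    stop_distance: float = 0.05
    altitude: float = 0.25
    altitude_wobble: float = 0.04

    # head saccades
    saccade_schedule: list[SaccadePlan] | None = None
    saccade_phase_in_downstroke: float = 0.75
    p_saccade_per_turn_beat: float = 0.8  # ~4-5 saccades per turn, as observed
    saccade_mean_amplitude: float = 30.0
    saccade_amplitude_sd: float = 10.0
    saccade_amplitude_range: tuple[float, float] = (15.0, 60.0)
    saccade_speed: float = 1500.0  # deg/s amplitude-duration slope
    saccade_duration_intercept_ms: float = 14.0  # duration = (A + intercept)/slope
    saccade_duration_jitter: float = 0.0
    head_drift: str = "auto"  # "auto": drift covers turn angle minus saccade sum

    # wingbeat modes
    wingbeat_plan: list[WingbeatPlan] | None = None
    normal_frequency: float = 17.0
    normal_frequency_sd: float = 0.8
    normal_ratio: float = 1.35
    normal_ratio_sd: float = 0.11
    intermittent_frequency: float = 9.5
    intermittent_frequency_sd: float = 0.5
    intermittent_ratio: float = 0.53
    intermittent_ratio_sd: float = 0.06
    p_intermittent: dict = field(
        default_factory=lambda: {"before_turn": 0.28, "during_turn": 0.12, "after_turn": 0.35}
    )

    # morphology / markers (m)
    wing_length: float = 0.135
    stroke_amplitude: float = 1.9  # rad, dorsal-to-ventral wingtip angle
    marker_separation: float = 0.016
    shoulder_width: float = 0.05
    neck_offset: float = 0.03

    # swinging perch (m, s)
    perch_swing_amplitude: float = 0.05  # fore-aft half excursion (~10 cm total)
    perch_side_amplitude: float = 0.005
    perch_period: float = 1.33
    perch_phase: float = 0.0

    # measurement noise: 3-D RMS of marker position error (m)
    noise_sigma: float = 0.0013

    # landing trigger: retinal perch extent threshold (deg); None disables
    landing_alpha_threshold: float | None = 55.0
    landing_init_time: float | None = None

    def validate(self) -> None:
        if self.turn_direction not in ("left", "right"):
            raise ConfigError("turn_direction must be 'left' or 'right'")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ConfigError("duration and sample_rate must be positive")
        if self.saccade_schedule is not None:
            plans = sorted(self.saccade_schedule, key=lambda p: p.start)
            for a, b in zip(plans, plans[1:]):
                if a.start + a.duration > b.start:
                    raise ConfigError(
                        f"overlapping saccades at t={a.start:.4f} and t={b.start:.4f}"
                    )
        for plan in self.wingbeat_plan or []:
            if plan.frequency <= 0:
                raise ConfigError("wingbeat frequencies must be positive")


@dataclass(frozen=True)
class TrueBeat:
    down_start: float
    down_mid: float
    down_end: float
    up_mid: float
    up_end: float
    mode: str
    frequency: float
    du_ratio: float
    phase_label: str


@dataclass
class GroundTruth:
    """Everything injected into one synthetic trial."""

    config: SyntheticTrialConfig
    t: np.ndarray
    phi_head: np.ndarray  # deg, noise-free, unwrapped
    phi_body: np.ndarray
    speed: np.ndarray  # m/s along path
    head_xy: np.ndarray  # noise-free planform head center
    saccades: list[SaccadePlan]
    beats: list[TrueBeat]
    turn_start: float
    turn_end: float
    landing_init_time: float | None
    alpha: np.ndarray | None  # deg, retinal perch extent, noise-free


@dataclass
class CohortTruth:
    template: SyntheticTrialConfig
    trial_truths: list[GroundTruth]

    @property
    def mode_parameters(self) -> dict:
        c = self.template
        return {
            "normal": {"frequency": c.normal_frequency, "frequency_sd": c.normal_frequency_sd,
                       "ratio": c.normal_ratio, "ratio_sd": c.normal_ratio_sd},
            "intermittent": {"frequency": c.intermittent_frequency,
                             "frequency_sd": c.intermittent_frequency_sd,
                             "ratio": c.intermittent_ratio, "ratio_sd": c.intermittent_ratio_sd},
        }


def _raised_cosine_step(u: np.ndarray) -> np.ndarray:
    """Smoothed unit step: integral of the raised-cosine velocity bump."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _blend(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Raised-cosine 0->1 transition centered after t0 over ``width`` seconds."""
    if width <= 0:
        return (t >= t0).astype(float)
    u = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _speed_profile(cfg: SyntheticTrialConfig, t: np.ndarray, t1: float, t2: float) -> np.ndarray:
    v = np.full_like(t, cfg.out_speed)
    v += (cfg.turn_speed - cfg.out_speed) * _blend(t, t1 - cfg.speed_blend / 2, cfg.speed_blend)
    v += (cfg.return_speed - cfg.turn_speed) * _blend(t, t2 - cfg.speed_blend / 2, cfg.speed_blend)
    return v


def _turn_ramp(t: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Raised-cosine heading ramp from 0 to 180 degrees over [t1, t2]."""
    u = np.clip((t - t1) / (t2 - t1), 0.0, 1.0)
    return 90.0 * (1.0 - np.cos(np.pi * u))


def _plan_wingbeats(cfg: SyntheticTrialConfig, rng: np.random.Generator,
                    t1: float, t2: float, t_end: float | None = None) -> list[TrueBeat]:
    beats: list[TrueBeat] = []
    dt = 1.0 / cfg.sample_rate
    t_end = cfg.duration if t_end is None else t_end

    def q(x: float) -> float:  # quantize to the sample grid, as frame-counted marks are
        return round(x / dt) * dt

    plan = list(cfg.wingbeat_plan) if cfg.wingbeat_plan is not None else None
    t0 = 0.0
    i = 0
    while True:
        if t0 <= t1:
            phase = "before_turn"
        elif t0 < t2:
            phase = "during_turn"
        else:
            phase = "after_turn"
        if plan is not None:
            if i >= len(plan):
                break
            p = plan[i]
            mode, freq, ratio = p.mode, p.frequency, p.du_ratio
        else:
            if rng.random() < cfg.p_intermittent[phase]:
                mode = "intermittent"
                freq = rng.normal(cfg.intermittent_frequency, cfg.intermittent_frequency_sd)
                ratio = rng.normal(cfg.intermittent_ratio, cfg.intermittent_ratio_sd)
            else:
                mode = "normal"
                freq = rng.normal(cfg.normal_frequency, cfg.normal_frequency_sd)
                ratio = rng.normal(cfg.normal_ratio, cfg.normal_ratio_sd)
            freq = max(freq, 1.0)
            ratio = max(ratio, 0.1)
        period = 1.0 / freq
        down = period * ratio / (1.0 + ratio)
        up = period - down
        marks = (t0, t0 + down / 2, t0 + down, t0 + down + up / 2, t0 + period)
        ds, dm, de, um, ue = (q(m) for m in marks)
        if ue >= t_end - dt:
            break
        if not (ds < dm < de < um < ue):  # pathological at very low sample rates
            break
        beats.append(TrueBeat(ds, dm, de, um, ue,
                              mode=mode, frequency=1.0 / (ue - ds),
                              du_ratio=(de - ds) / (ue - de), phase_label=phase))
        t0 = ue
        i += 1
    return beats


def _auto_saccade_schedule(cfg: SyntheticTrialConfig, rng: np.random.Generator,
                           beats: list[TrueBeat], t1: float, t2: float,
                           turn_sign: float) -> list[SaccadePlan]:
    candidates = []
    for b in beats:
        if b.phase_label != "during_turn":
            continue
        start = b.down_start + cfg.saccade_phase_in_downstroke * (b.down_end - b.down_start)
        if t1 <= start < t2:
            candidates.append(start)
    if not candidates:
        return []
    keep = rng.random(len(candidates)) < cfg.p_saccade_per_turn_beat
    if keep.sum() < min(2, len(candidates)):
        keep[: min(2, len(candidates))] = True
    starts = [s for s, k in zip(candidates, keep) if k]
    lo, hi = cfg.saccade_amplitude_range
    amps = np.clip(
        rng.normal(cfg.saccade_mean_amplitude, cfg.saccade_amplitude_sd, size=len(starts)),
        lo, hi,
    )
    amps *= 180.0 / amps.sum()  # saccades carry the whole turn; head holds in between
    plans = []
    for start, amp in zip(starts, amps):
        dur = (amp + cfg.saccade_duration_intercept_ms) / cfg.saccade_speed
        if cfg.saccade_duration_jitter > 0:
            dur *= max(0.3, 1.0 + cfg.saccade_duration_jitter * rng.standard_normal())
        plans.append(SaccadePlan(start=start, amplitude=turn_sign * amp, duration=dur))
    # clip overlaps caused by duration jitter
    cleaned: list[SaccadePlan] = []
    for p in plans:
        if cleaned and cleaned[-1].start + cleaned[-1].duration > p.start:
            prev = cleaned.pop()
            cleaned.append(dataclasses.replace(prev, duration=p.start - prev.start))
        cleaned.append(p)
    return cleaned


def _heading_unit(phi_deg: np.ndarray) -> np.ndarray:
    rad = np.deg2rad(phi_deg)
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


def _azimuthal_extent(head_xy: np.ndarray, edge_a: np.ndarray, edge_b: np.ndarray) -> np.ndarray:
    va = edge_a - head_xy
    vb = edge_b - head_xy
    ang = np.rad2deg(
        np.arctan2(va[:, 1], va[:, 0]) - np.arctan2(vb[:, 1], vb[:, 0])
    )
    return np.abs((ang + 180.0) % 360.0 - 180.0)


def generate_trial(
    cfg: SyntheticTrialConfig,
    geometry: ArenaGeometry | None = None,
    trial_id: str = "synthetic",
    bird_id: str | None = None,
) -> tuple[TrialRecording, GroundTruth]:
    """Build one synthetic trial and its ground truth.

    Deterministic for a given config (the config seed drives all draws).
    """
    cfg.validate()
    geometry = geometry or ArenaGeometry()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs
    sign = 1.0 if cfg.turn_direction == "left" else -1.0

    t1 = cfg.out_leg_length / cfg.out_speed
    t2 = t1 + cfg.turn_duration
    if t2 >= cfg.duration - 0.3:
        raise ConfigError("turn does not fit inside the trial duration")

    speed = _speed_profile(cfg, t, t1, t2)
    ramp = sign * _turn_ramp(t, t1, t2)

    # mirror the lane for right turns so the path stays inside the arena
    y0 = cfg.start_y if sign > 0 else geometry.width - cfg.start_y

    # stage 1: integrate out leg + turn to find the turn-exit position, then
    # aim the return leg at a point just in front of the perch center
    def integrate(theta: np.ndarray) -> np.ndarray:
        u = _heading_unit(theta)
        steps = (speed[:, None] * u) * dt
        pos = np.empty((n, 2))
        pos[0] = (cfg.start_x, y0)
        pos[1:] = pos[0] + np.cumsum(steps[:-1], axis=0)
        return pos

    pos = integrate(ramp)
    exit_idx = int(np.searchsorted(t, t2))
    px, py = geometry.perch_center
    aim = np.array([px + cfg.stop_distance, py])
    bearing = np.rad2deg(np.arctan2(aim[1] - pos[exit_idx, 1], aim[0] - pos[exit_idx, 0]))
    # unwrap the bearing next to the 180-degree turn exit heading
    correction = (bearing - sign * 180.0 + 180.0) % 360.0 - 180.0
    theta = ramp + correction * _blend(t, t2, 0.15)

    # stage 2: re-integrate; on the return leg the bird decelerates with
    # distance to the approach point and the trial ends on arrival
    head_u_path = _heading_unit(theta)
    stop_idx = n - 1
    for i in range(exit_idx, n - 1):
        d = float(np.hypot(*(aim - pos[i])))
        if d <= cfg.stop_distance:
            stop_idx = i
            break
        frac = np.clip((d - cfg.stop_distance)
                       / max(cfg.approach_taper_distance - cfg.stop_distance, 1e-6), 0.0, 1.0)
        v_des = cfg.final_speed + (cfg.return_speed - cfg.final_speed) * frac
        speed[i] = min(speed[i], v_des) if t[i] > t2 + cfg.speed_blend else speed[i]
        pos[i + 1] = pos[i] + speed[i] * head_u_path[i] * dt
    else:
        stop_idx = n - 1

    beats = _plan_wingbeats(cfg, rng, t1, t2, t_end=t[stop_idx])
    if len(beats) < 3:
        raise ConfigError("trial too short to contain wingbeats")
    # cut the recording at the last complete wingbeat so the wingbeat-rate
    # channels tile the whole trial
    n = int(round(beats[-1].up_end * fs)) + 1
    t = t[:n]
    speed = speed[:n]
    theta = theta[:n]
    ramp = ramp[:n]
    pos = pos[:n]

    margin = 0.01
    if (pos[:, 0].min() < margin or pos[:, 0].max() > geometry.length - margin
            or pos[:, 1].min() < margin or pos[:, 1].max() > geometry.width - margin):
        raise ConfigError("flight path leaves the arena; adjust speeds or durations")

    phi_body = theta  # body yaw follows the path tangent

    if cfg.saccade_schedule is not None:
        schedule = sorted(cfg.saccade_schedule, key=lambda p: p.start)
    else:
        schedule = _auto_saccade_schedule(cfg, rng, beats, t1, t2, sign)

    staircase = np.zeros(n)
    for plan in schedule:
        staircase += plan.amplitude * _raised_cosine_step((t - plan.start) / plan.duration)
    total_amp = sum(p.amplitude for p in schedule)
    if cfg.head_drift == "auto":
        # the turn ramp is carried by the saccades; any remainder drifts smoothly
        phi_head = theta - (total_amp / (sign * 180.0)) * ramp + staircase
    elif cfg.head_drift == "none":
        phi_head = staircase.copy()
    else:
        raise ConfigError(f"unknown head_drift mode {cfg.head_drift!r}")

    # altitude: slow smooth wobble well inside the 21 cm criterion
    z = cfg.altitude + cfg.altitude_wobble * np.sin(2.0 * np.pi * 0.7 * t / cfg.duration)

    head_u = _heading_unit(phi_head)
    body_u = _heading_unit(phi_body)
    left_u = _heading_unit(phi_body + 90.0)

    half = cfg.marker_separation / 2.0
    head_a = np.column_stack([pos + half * head_u, z])
    head_b = np.column_stack([pos - half * head_u, z])

    body_center = pos - cfg.neck_offset * body_u
    sh_l_xy = body_center + (cfg.shoulder_width / 2.0) * left_u
    sh_r_xy = body_center - (cfg.shoulder_width / 2.0) * left_u

    shoulder_l = np.full((n, 3), np.nan)
    shoulder_r = np.full((n, 3), np.nan)
    wingtip_l = np.full((n, 3), np.nan)
    wingtip_r = np.full((n, 3), np.nan)

    stroke_marks: list[tuple[float, str]] = []
    elev = {"down_start": cfg.stroke_amplitude / 2.0, "down_mid": 0.0,
            "down_end": -cfg.stroke_amplitude / 2.0, "up_mid": 0.0}
    r_wing = cfg.wing_length
    mark_times: list[tuple[str, float]] = []
    for b in beats:
        mark_times += [("down_start", b.down_start), ("down_mid", b.down_mid),
                       ("down_end", b.down_end), ("up_mid", b.up_mid)]
    # closing mark: the final beat's up_end is the next (unrecorded) beat's
    # down_start; annotating it lets readers close the last wingbeat
    mark_times.append(("down_start", beats[-1].up_end))
    for label, time in mark_times:
        idx = int(round(time * fs))
        if idx >= n:
            continue
        stroke_marks.append((t[idx], label))
        e = elev[label]
        planform = r_wing * np.cos(e)
        dz = r_wing * np.sin(e)
        shoulder_l[idx] = (*sh_l_xy[idx], z[idx] - 0.01)
        shoulder_r[idx] = (*sh_r_xy[idx], z[idx] - 0.01)
        wingtip_l[idx] = (*(sh_l_xy[idx] + planform * left_u[idx]), z[idx] - 0.01 + dz)
        wingtip_r[idx] = (*(sh_r_xy[idx] - planform * left_u[idx]), z[idx] - 0.01 + dz)

    # swinging perch track (planform center)
    wobble = 2.0 * np.pi * t / cfg.perch_period + cfg.perch_phase
    perch_track = np.column_stack([
        px + cfg.perch_swing_amplitude * np.sin(wobble),
        py + cfg.perch_side_amplitude * np.sin(wobble + np.pi / 2.0),
    ])

    half_w = geometry.perch_width / 2.0
    edge_l = perch_track + np.array([0.0, -half_w])
    edge_r = perch_track + np.array([0.0, half_w])
    alpha = _azimuthal_extent(pos, edge_l, edge_r)

    landing = cfg.landing_init_time
    if landing is None and cfg.landing_alpha_threshold is not None:
        after = (t > t2) & (alpha >= cfg.landing_alpha_threshold)
        landing = float(t[np.argmax(after)]) if after.any() else None

    # tracking noise: i.i.d. Gaussian per axis on every observed marker sample
    sigma_axis = cfg.noise_sigma / np.sqrt(3.0)

    def noisy(arr: np.ndarray) -> np.ndarray:
        if sigma_axis == 0:
            return arr
        out = arr.copy()
        obs = np.isfinite(arr)
        out[obs] += rng.normal(0.0, sigma_axis, size=int(obs.sum()))
        return out

    rec = TrialRecording(
        trial_id=trial_id,
        sample_rate=fs,
        t=t,
        head_a=noisy(head_a),
        head_b=noisy(head_b),
        shoulder_l=noisy(shoulder_l),
        shoulder_r=noisy(shoulder_r),
        wingtip_l=noisy(wingtip_l),
        wingtip_r=noisy(wingtip_r),
        stroke_marks=stroke_marks,
        landing_init_time=landing,
        perch_track=perch_track,
        bird_id=bird_id,
    )
    rec.validate()
    truth = GroundTruth(
        config=cfg, t=t, phi_head=phi_head, phi_body=phi_body, speed=speed,
        head_xy=pos, saccades=schedule, beats=beats,
        turn_start=t1, turn_end=t2, landing_init_time=landing, alpha=alpha,
    )
    return rec, truth


def generate_cohort(
    n_trials: int,
    template: SyntheticTrialConfig,
    seed: int,
    geometry: ArenaGeometry | None = None,
    n_birds: int = 5,
) -> tuple[list[tuple[TrialRecording, GroundTruth]], CohortTruth]:
    """Draw ``n_trials`` randomized trials around ``template``.

    Approach speeds and perch-swing phase vary across trials; saccade and
    wingbeat draws vary through per-trial seeds.  Trials are assigned
    round-robin to ``n_birds`` synthetic birds.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials + 1)
    meta_rng = np.random.default_rng(children[0])
    trials = []
    truths = []
    for i in range(n_trials):
        scale = float(np.clip(meta_rng.normal(1.0, 0.12), 0.7, 1.3))
        cfg = dataclasses.replace(
            template,
            seed=int(children[i + 1].generate_state(1)[0] % (2**31)),
            out_speed=template.out_speed * scale,
            return_speed=template.return_speed * float(np.clip(meta_rng.normal(1.0, 0.12), 0.7, 1.3)),
            perch_phase=float(meta_rng.uniform(0.0, 2.0 * np.pi)),
        )
        bird = f"bird{i % n_birds}"
        rec, truth = generate_trial(cfg, geometry=geometry,
                                    trial_id=f"trial{i:03d}", bird_id=bird)
        trials.append((rec, truth))
        truths.append(truth)
    return trials, CohortTruth(template=template, trial_truths=truths)
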