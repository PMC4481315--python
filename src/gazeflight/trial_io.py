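"""Trial recordings, arena geometry, and their plain-text file formats.

A trial is one U-turn flight in the arena: full-rate 3-D positions of the
two head markers, sparse (wingbeat-rate) shoulder and wingtip positions,
manually annotated stroke instants, the landing-initiation (tail-pitch)
time and, optionally, the planform track of the swinging perch.

Storage is a CSV (one row per video frame, meters/seconds, NaN for
unsampled frames of sparse channels) plus a YAML sidecar carrying the
scalar metadata and stroke marks.  The arena geometry lives in its own
YAML config.  All angles downstream are degrees; the planform frame has
x along the long arena axis pointing away from the perch (yaw 0) and
positive yaw meaning a leftward (counter-clockwise from above) rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

STROKE_LABELS = ("down_start", "down_mid", "down_end", "up_mid")
_NEXT_LABEL = {
    "down_start": "down_mid",
    "down_mid": "down_end",
    "down_end": "up_mid",
    "up_mid": "down_start",
}

_MARKER_COLUMNS = ("head_a", "head_b", "shoulder_l", "shoulder_r", "wingtip_l", "wingtip_r")


class TrialValidationError(ValueError):
    """A trial recording violates a structural invariant."""


class TrialParseError(ValueError):
    """A trial file could not be parsed."""


@dataclass
class ArenaGeometry:
    """Planform geometry of the flight arena and its visual features.

    Distances in meters.  The perch is a horizontal bar spanning the
    width direction near the x=0 end wall; the white (high-contrast)
    side wall is at y = width.
    """

    width: float = 0.6
    length: float = 1.0
    perch_x: float = 0.10
    perch_left_edge_y: float = 0.115
    perch_right_edge_y: float = 0.328
    gray_square_center_x: float = 0.5
    gray_square_width: float = 0.25

    @property
    def perch_width(self) -> float:
        return abs(self.perch_right_edge_y - self.perch_left_edge_y)

    @property
    def perch_center(self) -> tuple[float, float]:
        return (self.perch_x, 0.5 * (self.perch_left_edge_y + self.perch_right_edge_y))

    def features(self) -> dict[str, tuple[float, float]]:
        """Planform positions of the tracked visual features."""
        wall_y = self.width  # white side wall
        half = 0.5 * self.gray_square_width
        return {
            "corner_white_dark_front": (self.length, wall_y),
            "corner_white_dark_back": (0.0, wall_y),
            "gray_square_left": (self.gray_square_center_x - half, wall_y),
            "gray_square_right": (self.gray_square_center_x + half, wall_y),
            "perch_center": self.perch_center,
            "perch_left_edge": (self.perch_x, self.perch_left_edge_y),
            "perch_right_edge": (self.perch_x, self.perch_right_edge_y),
        }

    def validate(self) -> None:
        for name, (x, y) in self.features().items():
            if not (0.0 <= x <= self.length and 0.0 <= y <= self.width):
                raise TrialValidationError(f"feature {name} outside arena bounds")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "schema": "gazeflight-arena/1",
            "units": {"length": "m"},
            "width": self.width,
            "length": self.length,
            "perch_x": self.perch_x,
            "perch_left_edge_y": self.perch_left_edge_y,
            "perch_right_edge_y": self.perch_right_edge_y,
            "gray_square_center_x": self.gray_square_center_x,
            "gray_square_width": self.gray_square_width,
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaGeometry":
        data = yaml.safe_load(Path(path).read_text())
        kwargs = {
            k: float(data[k])
            for k in (
                "width",
                "length",
                "perch_x",
                "perch_left_edge_y",
                "perch_right_edge_y",
                "gray_square_center_x",
                "gray_square_width",
            )
            if k in data
        }
        geom = cls(**kwargs)
        geom.validate()
        return geom


@dataclass
class TrialRecording:
    """Raw per-frame kinematic time series for one flight plus annotations.

    Sparse channels (shoulders, wingtips) carry NaN at unsampled frames.
    ``perch_track`` is the planform (x, y) center of the swinging perch
    per frame, or None when only the rest position is known.
    """

    trial_id: str
    sample_rate: float
    t: np.ndarray
    head_a: np.ndarray
    head_b: np.ndarray
    shoulder_l: np.ndarray
    shoulder_r: np.ndarray
    wingtip_l: np.ndarray
    wingtip_r: np.ndarray
    stroke_marks: list[tuple[float, str]] = field(default_factory=list)
    landing_init_time: float | None = None
    perch_track: np.ndarray | None = None
    bird_id: str | None = None

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    @property
    def head_center(self) -> np.ndarray:
        return 0.5 * (self.head_a + self.head_b)

    def validate(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise TrialValidationError("time base must be a 1-D series of >=2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise TrialValidationError(
                f"time not strictly increasing at sample {bad + 1} (t={t[bad + 1]!r})"
            )
        if np.max(dt) > 1.01 * np.min(dt):
            raise TrialValidationError("sample intervals vary by more than 1%")
        if abs(np.median(dt) * self.sample_rate - 1.0) > 0.01:
            raise TrialValidationError(
                "declared sample_rate inconsistent with time base"
            )
        for name in _MARKER_COLUMNS:
            arr = getattr(self, name)
            if arr.shape != (t.size, 3):
                raise TrialValidationError(f"channel {name} must have shape (n, 3)")
            finite = np.isfinite(arr)
            rowwise = finite.all(axis=1) | (~finite).any(axis=1)
            # all-or-nothing per frame: a marker is either observed (finite
            # x,y,z) or fully missing
            if not np.all(finite.all(axis=1) | (~finite.all(axis=1))):
                raise TrialValidationError(f"channel {name} has partially missing frames")
            del rowwise
        if not np.isfinite(self.head_a).all() or not np.isfinite(self.head_b).all():
            raise TrialValidationError("head markers must be present at every frame")
        self._validate_stroke_marks()
        if self.perch_track is not None and self.perch_track.shape != (t.size, 2):
            raise TrialValidationError("perch_track must have shape (n, 2)")

    def _validate_stroke_marks(self) -> None:
        prev_t = -np.inf
        prev_label: str | None = None
        for time, label in self.stroke_marks:
            if label not in STROKE_LABELS:
                raise TrialValidationError(f"unknown stroke label {label!r}")
            if time <= prev_t:
                raise TrialValidationError(
                    f"stroke marks not strictly increasing at t={time}"
                )
            if prev_label is not None and label != _NEXT_LABEL[prev_label]:
                raise TrialValidationError(
                    f"illegal stroke order: {prev_label!r} followed by {label!r}"
                )
            prev_t, prev_label = time, label


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".yaml")


def write_trial(rec: TrialRecording, path: str | Path) -> Path:
    """Write a trial as CSV + YAML sidecar; returns the CSV path."""
    rec.validate()
    path = Path(path)
    cols: dict[str, np.ndarray] = {"t": rec.t}
    for name in _MARKER_COLUMNS:
        arr = getattr(rec, name)
        for i, axis in enumerate("xyz"):
            cols[f"{name}_{axis}"] = arr[:, i]
    if rec.perch_track is not None:
        cols["perch_x"] = rec.perch_track[:, 0]
        cols["perch_y"] = rec.perch_track[:, 1]
    frame = pd.DataFrame(cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# gazeflight trial; units: t=s, positions=m\n")
        frame.to_csv(fh, index=False, float_format="%.12g")
    meta: dict = {
        "schema": "gazeflight-trial/1",
        "trial_id": rec.trial_id,
        "sample_rate": float(rec.sample_rate),
        "stroke_marks": [[float(t), label] for t, label in rec.stroke_marks],
    }
    if rec.bird_id is not None:
        meta["bird_id"] = rec.bird_id
    if rec.landing_init_time is not None:
        meta["landing_init_time"] = float(rec.landing_init_time)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_trial(path: str | Path, config: ArenaGeometry | None = None) -> TrialRecording:
    """Read a trial CSV (+ YAML sidecar) and validate it.

    ``config`` is accepted for interface symmetry with the CLI stages; the
    geometry is not needed to parse a trial.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrialParseError(f"could not parse {path}: {exc}") from exc
    required = ["t"] + [f"{m}_{ax}" for m in _MARKER_COLUMNS for ax in "xyz"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TrialParseError(f"{path} missing columns: {missing}")
    bad_rows = frame[required].apply(pd.to_numeric, errors="coerce")
    # t must be numeric everywhere; markers may be NaN but not non-numeric junk
    if bad_rows["t"].isna().any():
        row = int(bad_rows["t"].isna().idxmax())
        raise TrialParseError(f"{path}: malformed time value at data row {row}")
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise TrialParseError(f"missing sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    markers = {
        name: frame[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy(dtype=float)
        for name in _MARKER_COLUMNS
    }
    perch_track = None
    if "perch_x" in frame.columns and "perch_y" in frame.columns:
        perch_track = frame[["perch_x", "perch_y"]].to_numpy(dtype=float)
    rec = TrialRecording(
        trial_id=str(meta["trial_id"]),
        sample_rate=float(meta["sample_rate"]),
        t=frame["t"].to_numpy(dtype=float),
        stroke_marks=[(float(t), str(lab)) for t, lab in meta.get("stroke_marks", [])],
        landing_init_time=(
            float(meta["landing_init_time"]) if "landing_init_time" in meta else None
        ),
        perch_track=perch_track,
        bird_id=meta.get("bird_id"),
        **markers,
    )
    rec.validate()
    return rec
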