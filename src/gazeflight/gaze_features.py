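"""Azimuthal positions of arena features relative to head yaw.

The azimuth of a feature is the signed planform angle from the head-yaw
heading vector to the head-to-feature vector, in (-180, 180]; positive
azimuths lie in the left visual hemisphere.  Distributions are built
from intersaccadic samples only (head orientation approximately
constant): at full rate via the complement of detected saccades, or on
wingbeat-rate data by excluding beats whose within-beat yaw SD exceeds
10 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .saccades import SaccadeEvent
from .trial_io import ArenaGeometry

AZIMUTH_BINS = np.arange(-90.0, 91.0, 10.0)


def _wrap180(a):
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class FeatureAzimuthSeries:
    """Per-feature azimuth time series for one flight."""

    t: np.ndarray
    azimuth: dict[str, np.ndarray]  # feature id -> deg, (-180, 180]
    valid: dict[str, np.ndarray]  # feature id -> bool (False near coincidence)
    phase_label: np.ndarray | None = None  # per-sample flight phase
    intersaccadic_mask: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def features(self) -> list[str]:
        return list(self.azimuth)


def feature_azimuths(
    head_xy: np.ndarray,
    phi_head: np.ndarray,
    geometry: ArenaGeometry,
    perch_track: np.ndarray | None = None,
    t: np.ndarray | None = None,
) -> FeatureAzimuthSeries:
    """Signed azimuth of every arena feature relative to head yaw.

    With ``perch_track`` the three perch features follow the swinging
    perch; otherwise the rest position from the geometry is used.
    Samples where the head coincides with a feature point are masked.
    """
    head_xy = np.asarray(head_xy, dtype=float)
    n = head_xy.shape[0]
    if t is None:
        t = np.arange(n, dtype=float)
    positions: dict[str, np.ndarray] = {
        name: np.broadcast_to(np.asarray(p, dtype=float), (n, 2))
        for name, p in geometry.features().items()
    }
    if perch_track is not None:
        perch_track = np.asarray(perch_track, dtype=float)
        half_w = geometry.perch_width / 2.0
        positions["perch_center"] = perch_track
        positions["perch_left_edge"] = perch_track + np.array([0.0, -half_w])
        positions["perch_right_edge"] = perch_track + np.array([0.0, half_w])

    azimuth: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for name, pos in positions.items():
        vec = pos - head_xy
        dist = np.hypot(vec[:, 0], vec[:, 1])
        ok = dist > 1e-9
        az = np.full(n, np.nan)
        az[ok] = _wrap180(
            np.rad2deg(np.arctan2(vec[ok, 1], vec[ok, 0])) - phi_head[ok]
        )
        azimuth[name] = az
        valid[name] = ok
    return FeatureAzimuthSeries(t=t, azimuth=azimuth, valid=valid)


def intersaccadic_mask_fullrate(t: np.ndarray, events: list[SaccadeEvent]) -> np.ndarray:
    """True outside every detected saccade's extended boundaries."""
    mask = np.ones(t.size, dtype=bool)
    for ev in events:
        mask &= ~((t >= ev.start) & (t <= ev.end))
    return mask


def intersaccadic_mask_lowres(
    t_samples: np.ndarray,
    phi_samples: np.ndarray,
    beat_windows: list[tuple[float, float]],
    sd_threshold: float = 10.0,
) -> np.ndarray:
    """Per-sample mask for wingbeat-rate yaw data.

    A wingbeat is excluded entirely when the SD of the yaw samples inside
    it exceeds ``sd_threshold`` degrees; samples outside any beat, or in
    beats with fewer than two samples, are excluded with a warning.
    """
    t_samples = np.asarray(t_samples, dtype=float)
    phi_samples = np.asarray(phi_samples, dtype=float)
    mask = np.zeros(t_samples.size, dtype=bool)
    short_beats = 0
    for start, end in beat_windows:
        sel = (t_samples >= start) & (t_samples < end)
        count = int(sel.sum())
        if count < 2:
            short_beats += 1
            continue
        if float(np.std(phi_samples[sel])) <= sd_threshold:
            mask[sel] = True
    if short_beats:
        warnings.warn(f"{short_beats} wingbeats had <2 yaw samples and were excluded")
    return mask


def azimuth_histogram(
    series: FeatureAzimuthSeries,
    phase: str | None = None,
    bins: np.ndarray = AZIMUTH_BINS,
) -> pd.DataFrame:
    """Raw intersaccadic azimuth counts per feature for one flight.

    Bins are left-closed; azimuths outside the binning range are dropped
    from the histogram (but remain in the series).
    """
    base = (series.intersaccadic_mask if series.intersaccadic_mask is not None
            else np.ones(series.t.size, dtype=bool))
    if phase is not None:
        if series.phase_label is None:
            raise ValueError("series has no phase labels")
        base = base & (series.phase_label == phase)
    rows = []
    for name, az in series.azimuth.items():
        sel = base & series.valid[name] & np.isfinite(az)
        counts, _ = np.histogram(az[sel], bins=bins)
        for left, c in zip(bins[:-1], counts):
            rows.append({"feature": name, "bin_left": left, "count": int(c)})
    return pd.DataFrame(rows)


def azimuth_distributions(
    per_bird_series: dict[str, list[FeatureAzimuthSeries]],
    phase: str | None = None,
    bins: np.ndarray = AZIMUTH_BINS,
    normalization: str = "all_features",
) -> pd.DataFrame:
    """Normalized per-phase feature-azimuth distributions averaged over birds.

    Per bird, flight histograms are summed and each feature's counts are
    divided by the summed counts across all features of that phase
    (``normalization="all_features"``) or across the other features only
    (``"other_features"``).  The per-bird distributions are then averaged
    across birds; a peak summary (bin and height per feature) rides along.
    """
    if normalization not in ("all_features", "other_features"):
        raise ValueError(f"unknown normalization {normalization!r}")
    per_bird_tables = []
    for bird, series_list in per_bird_series.items():
        tables = []
        for series in series_list:
            table = azimuth_histogram(series, phase=phase, bins=bins)
            if not table.empty:
                tables.append(table)
        if not tables:
            warnings.warn(f"bird {bird}: no samples in phase {phase!r}")
            continue
        counts = (pd.concat(tables).groupby(["feature", "bin_left"])["count"]
                  .sum().reset_index())
        total = counts["count"].sum()
        if total == 0:
            warnings.warn(f"bird {bird}: no samples in phase {phase!r}")
            continue
        norm = []
        for feature, grp in counts.groupby("feature"):
            denom = total - grp["count"].sum() if normalization == "other_features" else total
            denom = denom if denom > 0 else np.nan
            g = grp.copy()
            g["density"] = g["count"] / denom
            norm.append(g)
        table = pd.concat(norm)
        table["bird"] = bird
        per_bird_tables.append(table)
    if not per_bird_tables:
        warnings.warn(f"no data in phase {phase!r}")
        return pd.DataFrame()
    merged = pd.concat(per_bird_tables)
    return (merged.groupby(["feature", "bin_left"])["density"]
            .mean().reset_index())


def distribution_peaks(distributions: pd.DataFrame) -> pd.DataFrame:
    """Peak bin (left edge) and height per feature."""
    rows = []
    for feature, grp in distributions.groupby("feature"):
        k = grp["density"].idxmax()
        rows.append({"feature": feature,
                     "peak_bin_left": float(grp.loc[k, "bin_left"]),
                     "peak_density": float(grp.loc[k, "density"])})
    return pd.DataFrame(rows)
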