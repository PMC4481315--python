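"""Shared fixtures: synthetic cohorts, derived pipelines, detector oracle."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from gazeflight import kinematics, saccades, synth
from gazeflight.kinematics import YawTraces
from gazeflight.trial_io import ArenaGeometry


@pytest.fixture(scope="session")
def geometry() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture(scope="session")
def cohort16():
    """16 randomized trials at study conditions (default config, seed 11)."""
    trials, truth = synth.generate_cohort(16, synth.SyntheticTrialConfig(), seed=11)
    return trials, truth


@pytest.fixture(scope="session")
def pipeline16(cohort16):
    """Yaw traces, saccade events and wingbeat records for the 16-trial cohort."""
    trials, _ = cohort16
    out = []
    for rec, truth in trials:
        yaw = kinematics.compute_yaw(rec)
        events = saccades.detect_saccades(yaw)
        beats = kinematics.wingbeat_records(rec, yaw=yaw)
        out.append({"rec": rec, "truth": truth, "yaw": yaw,
                    "events": events, "beats": beats})
    return out


@pytest.fixture(scope="session")
def beat_table(pipeline16) -> pd.DataFrame:
    rows = []
    for item in pipeline16:
        for b, tb in zip(item["beats"].itertuples(), item["truth"].beats):
            rows.append({
                "bird": item["rec"].bird_id,
                "flight": item["rec"].trial_id,
                "frequency": b.frequency,
                "du_ratio": b.du_ratio,
                "true_mode": tb.mode,
                "phase_label": tb.phase_label,
            })
    return pd.DataFrame(rows)


def yaw_from_omega(omega: np.ndarray, fs: float = 2000.0) -> YawTraces:
    """Wrap a velocity trace as YawTraces (yaw integrated from omega)."""
    omega = np.asarray(omega, dtype=float)
    n = omega.size
    t = np.arange(n) / fs
    phi = np.concatenate([[0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1]) / fs)])
    zeros = np.zeros(n)
    return YawTraces(t=t, sample_rate=fs, phi_head=phi, phi_body=zeros,
                     phi_diff=phi, omega_head=omega, speed=zeros,
                     head_xy=np.zeros((n, 2)))


def brute_force_runs(omega: np.ndarray, fs: float, threshold: float = 400.0,
                     min_duration_ms: float = 12.0) -> list[tuple[int, int]]:
    """Independent scan for supra-threshold runs (start, stop) in samples."""
    min_n = int(round(min_duration_ms / 1000.0 * fs))
    runs = []
    i, n = 0, len(omega)
    while i < n:
        if abs(omega[i]) > threshold:
            j = i
            while j < n and abs(omega[j]) > threshold:
                j += 1
            if j - i >= min_n:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def quiet_segmentation(rec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kinematics.segment_turn(rec)
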