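"""Feature azimuth geometry, intersaccadic masks and distributions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeflight import gaze_features, kinematics, saccades
from gazeflight.gaze_features import (
    azimuth_distributions,
    azimuth_histogram,
    distribution_peaks,
    feature_azimuths,
    intersaccadic_mask_fullrate,
    intersaccadic_mask_lowres,
)
from gazeflight.trial_io import ArenaGeometry


class TestFeatureAzimuths:
    def test_feature_dead_ahead_is_zero(self, geometry):
        # head below the gray square center, looking straight at the wall
        target = np.array(geometry.features()["gray_square_left"])
        head = np.array([[target[0], 0.2]])
        series = feature_azimuths(head, np.array([90.0]), geometry)
        assert series.azimuth["gray_square_left"][0] == pytest.approx(0.0, abs=1e-9)

    def test_left_right_sign_convention(self, geometry):
        target = np.array(geometry.features()["perch_center"])
        head = target + np.array([0.3, 0.0])  # feature due -x of the head
        # facing +y (north): left hand points -x, so the perch is leftward
        series = feature_azimuths(head[None, :], np.array([90.0]), geometry)
        assert series.azimuth["perch_center"][0] == pytest.approx(90.0)
        # facing -y (south): the same feature is to the bird's right
        series = feature_azimuths(head[None, :], np.array([-90.0]), geometry)
        assert series.azimuth["perch_center"][0] == pytest.approx(-90.0)

    def test_perch_centered_when_facing_it_from_midline(self, geometry):
        px, py = geometry.perch_center
        head = np.array([[px + 0.45, py]])
        series = feature_azimuths(head, np.array([180.0]), geometry)
        assert series.azimuth["perch_center"][0] == pytest.approx(0.0, abs=1e-9)
        # edges straddle the center seen head-on
        left = series.azimuth["perch_left_edge"][0]
        right = series.azimuth["perch_right_edge"][0]
        assert left < 0 < right or right < 0 < left

    def test_translation_along_heading_keeps_feature_ahead(self, geometry):
        target = np.array(geometry.features()["perch_center"])
        for d in (0.1, 0.25, 0.5):
            head = target + np.array([d, 0.0])
            series = feature_azimuths(head[None, :], np.array([180.0]), geometry)
            assert series.azimuth["perch_center"][0] == pytest.approx(0.0, abs=1e-9)

    def test_coincident_feature_masked(self, geometry):
        head = np.array([list(geometry.perch_center)])
        series = feature_azimuths(head, np.array([0.0]), geometry)
        assert not series.valid["perch_center"][0]
        assert np.isnan(series.azimuth["perch_center"][0])

    @given(delta=st.floats(min_value=-170.0, max_value=170.0),
           seed=st.integers(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_yaw_shift_equivariance(self, delta, seed, geometry):
        """Rotating yaw by +delta shifts all azimuths by exactly -delta."""
        rng = np.random.default_rng(seed)
        head = rng.uniform([0.15, 0.1], [0.9, 0.5], size=(6, 2))
        phi = rng.uniform(-180, 180, size=6)
        base = feature_azimuths(head, phi, geometry)
        shifted = feature_azimuths(head, phi + delta, geometry)
        for name in base.features():
            expect = (base.azimuth[name] - delta + 180.0) % 360.0 - 180.0
            got = shifted.azimuth[name]
            diff = (got - expect + 180.0) % 360.0 - 180.0
            np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    def test_moving_perch_tracks_instantaneous_position(self, geometry):
        head = np.array([[0.6, 0.2215], [0.6, 0.2215]])
        phi = np.array([180.0, 180.0])
        track = np.array([[0.10, 0.2215], [0.10, 0.30]])
        series = feature_azimuths(head, phi, geometry, perch_track=track)
        assert series.azimuth["perch_center"][0] == pytest.approx(0.0, abs=1e-9)
        assert series.azimuth["perch_center"][1] != pytest.approx(0.0, abs=1.0)


class TestIntersaccadicMasks:
    def test_lowres_keeps_quiet_beats_drops_jumps(self):
        t = np.arange(8) * 0.01
        phi = np.array([0.0, 0.1, 0.0, 0.1, 10.0, 50.0, 49.0, 50.0])
        windows = [(0.0, 0.04), (0.04, 0.08)]
        mask = intersaccadic_mask_lowres(t, phi, windows)
        assert mask[:4].all()  # SD ~ 0.05 deg
        assert not mask[4:].any()  # 40-deg jump inside the beat

    def test_short_beats_excluded_with_warning(self):
        t = np.array([0.0, 0.05])
        phi = np.array([0.0, 1.0])
        with pytest.warns(UserWarning, match="<2"):
            mask = intersaccadic_mask_lowres(t, phi, [(0.0, 0.01), (0.01, 0.1)])
        assert not mask[0]

    def test_fullrate_mask_complements_events(self, pipeline16):
        item = pipeline16[0]
        mask = intersaccadic_mask_fullrate(item["rec"].t, item["events"])
        for ev in item["events"]:
            sel = (item["rec"].t >= ev.start) & (item["rec"].t <= ev.end)
            assert not mask[sel].any()
        assert mask.sum() > 0.5 * mask.size


def _cohort_series(pipeline16, geometry, lowres=False):
    per_bird = {}
    for item in pipeline16:
        rec, yaw = item["rec"], item["yaw"]
        if not lowres:
            s = feature_azimuths(yaw.head_xy, yaw.phi_head, geometry,
                                 perch_track=rec.perch_track, t=rec.t)
            s.intersaccadic_mask = intersaccadic_mask_fullrate(rec.t, item["events"])
        else:
            mark_t = np.array([m[0] for m in rec.stroke_marks])
            idx = np.round(mark_t * rec.sample_rate).astype(int)
            windows = [(b.down_start, b.up_end) for b in item["truth"].beats]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = intersaccadic_mask_lowres(mark_t, yaw.phi_head[idx], windows)
            s = feature_azimuths(yaw.head_xy[idx], yaw.phi_head[idx], geometry,
                                 perch_track=rec.perch_track[idx], t=mark_t)
            s.intersaccadic_mask = mask
        seg = kinematics.segment_turn(rec)
        labels = np.full(s.t.size, "after_turn", dtype=object)
        labels[s.t < seg.turn_start] = "before_turn"
        labels[(s.t >= seg.turn_start) & (s.t <= seg.turn_end)] = "during_turn"
        s.phase_label = labels
        per_bird.setdefault(rec.bird_id, []).append(s)
    return per_bird


class TestDistributions:
    def test_single_peak_for_fixated_feature(self, geometry):
        n = 50
        target = np.array(geometry.features()["perch_center"])
        head = np.tile(target + [0.4, 0.0], (n, 1))
        series = feature_azimuths(head, np.full(n, 180.0), geometry)
        hist = azimuth_histogram(series)
        perch = hist[hist.feature == "perch_center"]
        assert perch["count"].sum() == n
        assert perch.loc[perch.bin_left == 0.0, "count"].iloc[0] == n

    def test_uniform_azimuths_flat_histogram(self, geometry):
        n = 1800
        target = np.array(geometry.features()["perch_center"])
        head = np.tile(target + [0.4, 0.0], (n, 1))
        phi = 180.0 + np.repeat(np.arange(-90, 90), 10) + 0.5
        series = feature_azimuths(head, phi, geometry)
        hist = azimuth_histogram(series)
        perch = hist[hist.feature == "perch_center"]
        assert perch["count"].nunique() == 1  # identical mass in every bin

    def test_perch_center_stabilized_after_turn(self, pipeline16, geometry):
        """After the turn the perch center peaks frontally; the flanking
        edges are broader with lower peaks."""
        per_bird = _cohort_series(pipeline16, geometry)
        dist = azimuth_distributions(per_bird, phase="after_turn")
        peaks = distribution_peaks(dist).set_index("feature")
        assert abs(peaks.loc["perch_center", "peak_bin_left"]) <= 10.0
        for edge in ("perch_left_edge", "perch_right_edge"):
            assert peaks.loc[edge, "peak_density"] < peaks.loc["perch_center", "peak_density"]

    def test_normalized_mass_at_most_one(self, pipeline16, geometry):
        per_bird = _cohort_series(pipeline16, geometry)
        dist = azimuth_distributions(per_bird, phase="during_turn")
        for _, grp in dist.groupby("feature"):
            assert grp["density"].sum() <= 1.0 + 1e-9

    def test_other_features_normalization_option(self, pipeline16, geometry):
        per_bird = {k: v for k, v in list(
            _cohort_series(pipeline16, geometry).items())[:2]}
        a = azimuth_distributions(per_bird, phase="after_turn",
                                  normalization="all_features")
        b = azimuth_distributions(per_bird, phase="after_turn",
                                  normalization="other_features")
        merged = a.merge(b, on=["feature", "bin_left"], suffixes=("_all", "_other"))
        # denominators differ, relative ordering within a feature does not
        assert (merged["density_other"] >= merged["density_all"] - 1e-12).all()

    def test_lowres_distributions_track_fullrate(self, pipeline16, geometry):
        """Wingbeat-rate sampling with the 10-deg SD rule reproduces the
        full-rate intersaccadic feature distributions (r > 0.9)."""
        full = azimuth_distributions(_cohort_series(pipeline16, geometry))
        low = azimuth_distributions(_cohort_series(pipeline16, geometry, lowres=True))
        merged = full.merge(low, on=["feature", "bin_left"], suffixes=("_f", "_l"))
        for feature, grp in merged.groupby("feature"):
            r = np.corrcoef(grp["density_f"], grp["density_l"])[0, 1]
            assert r > 0.9, feature

    def test_empty_phase_warned(self, geometry):
        series = feature_azimuths(np.array([[0.5, 0.3]]), np.array([0.0]), geometry)
        series.phase_label = np.array(["after_turn"], dtype=object)
        with pytest.warns(UserWarning, match="no (data|samples)"):
            out = azimuth_distributions({"b": [series]}, phase="during_turn")
        assert out.empty
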