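"""Contraction metrics: masks, areas, BPM, CV, heat maps, group stats."""

import numpy as np
import pytest

from ardic import metrics
from ardic.metrics import (
    SARCOMERE_UM,
    beating_area,
    bpm_fft,
    bpm_peaks,
    compare_cv_groups,
    contraction_mask,
    contraction_volume,
    cv_split,
    displacement_signal,
    heatmaps,
)
from ardic.piv import DisplacementField


def _field(mag_px, valid=None, frame=1):
    mag_px = np.asarray(mag_px, dtype=float)
    if valid is None:
        valid = np.ones(mag_px.shape, dtype=bool)
    return DisplacementField(
        grid_x=np.arange(mag_px.shape[1]) * 24.0,
        grid_y=np.arange(mag_px.shape[0]) * 24.0,
        u=mag_px,
        v=np.zeros_like(mag_px),
        quality=np.ones(mag_px.shape),
        valid=valid,
        frame_index=frame,
    )


PX = 1.0  # 1 um/px keeps the arithmetic transparent


class TestMask:
    def test_zero_field_empty(self):
        assert not contraction_mask(_field(np.zeros((4, 4))), PX).any()

    def test_threshold_ordering(self):
        f = _field(np.full((4, 4), 0.15))
        assert contraction_mask(f, PX, 0.14).all()
        assert not contraction_mask(f, PX, 0.56).any()

    def test_invalid_vectors_excluded(self):
        valid = np.ones((3, 3), dtype=bool)
        valid[0, 0] = False
        f = _field(np.ones((3, 3)), valid)
        assert not contraction_mask(f, PX)[0, 0]

    def test_monotone_in_threshold(self, rng):
        f = _field(rng.uniform(0, 1, size=(8, 8)))
        lo = contraction_mask(f, PX, 0.14)
        hi = contraction_mask(f, PX, 0.56)
        assert (hi <= lo).all()  # raising the threshold never grows the mask

    def test_alternate_threshold_is_four_sarcomeres(self):
        assert 0.56 == pytest.approx(4 * SARCOMERE_UM)


class TestBeatingArea:
    def test_empty_and_full(self):
        empty = np.zeros((5, 5), dtype=bool)
        assert beating_area(empty, 532.6) == (0.0, 0.0)
        full = np.ones((5, 5), dtype=bool)
        assert beating_area(full, 532.6)[1] == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask.ravel()[:100] = True
        area, cov = beating_area(mask, 532.6, n_valid=400)
        assert area == pytest.approx(53260.0)
        assert cov == pytest.approx(25.0)


class TestBpm:
    @pytest.mark.parametrize("f_hz,expected", [(0.5, 30), (0.75, 45),
                                               (1.0, 60), (1.25, 75), (2.0, 120)])
    def test_fft_recovers_rate(self, f_hz, expected):
        t = np.arange(0, 60, 0.2)
        sig = np.clip(np.cos(2 * np.pi * f_hz * t + np.pi), 0, None) ** 2
        est = bpm_fft(sig, 5.0)
        assert est.bpm == pytest.approx(expected, abs=0.5)
        assert est.reliable

    def test_flat_signal_reports_absent(self):
        est = bpm_fft(np.ones(300), 5.0)
        assert est.bpm is None

    def test_white_noise_flagged_unreliable(self, rng):
        flags = [bpm_fft(rng.normal(size=300), 5.0).reliable
                 for _ in range(50)]
        assert not any(flags)

    def test_peak_counter_hand_case(self):
        """10 clean pulses in 8 s count as 75 BPM."""
        t = np.arange(0, 8, 0.2)
        sig = np.clip(np.cos(2 * np.pi * 1.25 * t), 0, None) ** 2
        assert bpm_peaks(sig, 5.0) == pytest.approx(75.0, abs=8)

    def test_monotone_ramp_counts_nothing(self):
        assert bpm_peaks(np.linspace(0, 1, 100), 5.0) == 0.0

    def test_estimators_agree_on_clean_trains(self):
        for f_hz in (0.5, 0.75, 1.0, 1.25):
            t = np.arange(0, 60, 0.2)
            sig = np.clip(np.cos(2 * np.pi * f_hz * t + np.pi), 0, None) ** 2
            assert abs(bpm_fft(sig, 5.0).bpm - bpm_peaks(sig, 5.0)) <= 5.0


class TestContractionVolume:
    def test_empty_mask_zero(self):
        f = _field(np.ones((4, 4)))
        assert contraction_volume(f, np.zeros((4, 4), bool), PX) == 0.0

    def test_reduces_to_sum_at_default_areas(self):
        f = _field(np.zeros((3, 3)))
        f.u[0, :3] = 1.0
        mask = f.u > 0
        assert contraction_volume(f, mask, PX) == pytest.approx(3.0)

    def test_matches_brute_force(self, rng):
        mag = rng.uniform(0, 3, size=(6, 6))
        f = _field(mag)
        mask = mag > 1.0
        block, norm = 700.0, 532.6
        brute = sum(mag[i, j] * block / norm
                    for i in range(6) for j in range(6) if mask[i, j])
        assert contraction_volume(f, mask, PX, block, norm) == pytest.approx(brute)


class TestCvSplit:
    def test_constant_series_all_high(self):
        high, _ = cv_split(np.full(10, 3.0))
        assert high.all()

    def test_single_spike(self):
        cv = np.array([0.0, 0.0, 0.0, 10.0])
        high, cutoff = cv_split(cv)
        assert cutoff == pytest.approx(10.0 - cv.std())
        assert list(high) == [False, False, False, True]

    def test_scale_invariant_labels(self, rng):
        cv = rng.uniform(0, 5, size=30)
        a, _ = cv_split(cv)
        b, _ = cv_split(cv * 37.5)
        assert np.array_equal(a, b)


class TestHeatmaps:
    def test_static_stack_zero_maps(self):
        fields = [_field(np.zeros((4, 4)), frame=k) for k in range(5)]
        freq, mag = heatmaps(fields, PX)
        assert not freq.any() and not mag.any()

    def test_half_duty_point(self):
        fields = []
        for k in range(10):
            m = np.zeros((4, 4))
            if k % 2 == 0:
                m[2, 2] = 1.0
            fields.append(_field(m, frame=k))
        freq, mag = heatmaps(fields, PX)
        assert freq[2, 2] == pytest.approx(0.5)

    def test_frequency_and_magnitude_centres_can_differ(self):
        """Equal duty cycles, unequal amplitudes: same frequency maxima,
        different magnitude maxima."""
        fields = []
        for k in range(10):
            m = np.zeros((4, 4))
            if k % 2 == 0:
                m[1, 1] = 1.0  # weak origin
                m[2, 2] = 3.0  # strong origin
            fields.append(_field(m, frame=k))
        freq, mag = heatmaps(fields, PX)
        assert freq[1, 1] == pytest.approx(freq[2, 2])
        assert mag[2, 2] > mag[1, 1]

    def test_frame_order_invariance(self, rng):
        fields = [_field(rng.uniform(0, 1, (4, 4)), frame=k) for k in range(8)]
        f1, m1 = heatmaps(fields, PX)
        f2, m2 = heatmaps(fields[::-1], PX)
        assert np.allclose(f1, f2) and np.allclose(m1, m2)

    def test_bounds(self, beating_run):
        freq, mag = heatmaps(beating_run["fields"],
                             beating_run["stack"].pixel_size_um)
        assert freq.min() >= 0.0 and freq.max() <= 1.0
        assert mag.min() >= 0.0


class TestDisplacementSignal:
    def test_no_active_points_gives_nan_signal(self):
        fields = [_field(np.zeros((4, 4)), frame=k) for k in range(5)]
        sig = displacement_signal(fields, PX)
        assert np.isnan(sig).all()

    def test_signal_tracks_envelope(self, beating_run):
        sig = displacement_signal(beating_run["fields"],
                                  beating_run["stack"].pixel_size_um)
        env = beating_run["truth"].origin_envelopes[0][1:]
        assert np.corrcoef(sig, env)[0, 1] > 0.95


class TestCvGroups:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.uniform(1, 2, size=10)
        series = np.concatenate([x, x])
        labels = np.array([True] * 10 + [False] * 10)
        out = compare_cv_groups(series, series, -series, labels)
        p = out.loc[out.quantity == "max_speed_um_s", "welch_p"].iloc[0]
        assert p > 0.9

    def test_planted_difference_detected(self, rng):
        low = rng.normal(1.0, 0.05, size=15)
        high = rng.normal(10.0, 0.05, size=15)
        series = np.concatenate([high, low])
        labels = np.array([True] * 15 + [False] * 15)
        out = compare_cv_groups(series, series, -series, labels)
        assert (out["welch_p"].dropna() < 1e-3).all()

    def test_sem_matches_brute_force(self, rng):
        x = rng.normal(size=12)
        labels = np.array([True] * 12)
        out = compare_cv_groups(x, x, x, labels)
        sem = out.loc[(out.group == "high") & (out.quantity == "max_speed_um_s"),
                      "sem"].iloc[0]
        brute = np.sqrt(((x - x.mean()) ** 2).sum() / (len(x) - 1)) / np.sqrt(len(x))
        assert sem == pytest.approx(brute, rel=1e-12)
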