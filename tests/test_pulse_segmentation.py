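import numpy as np
import pytest

from motorseg.kinematics import compute_derivatives
from motorseg.pulse_segmentation import (
    Pulse,
    detect_pulses,
    extract_boundaries,
    segment_count,
    segment_pulse,
    time_to_f90,
    zero_crossings,
)

from .conftest import analyzed_pulse, burst_train, make_recording, triangular_pulse

FS = 200.0


def brute_threshold_onset(force, rfd, peak, threshold=20.0, base_frac=0.05):
    """Independent backward scan for the onset of a detected pulse."""
    i = peak
    while i > 0 and (rfd[i - 1] >= threshold or force[i - 1] >= base_frac * force[peak]):
        i -= 1
    return i


class TestDetectPulses:
    def test_flat_recording_yields_nothing(self):
        rec = make_recording(np.zeros(1000))
        assert detect_pulses(rec, compute_derivatives(rec)) == []

    def test_single_triangular_pulse(self):
        force, ramp_start = triangular_pulse()
        rec = make_recording(force)
        deriv = compute_derivatives(rec)
        pulses = detect_pulses(rec, deriv)
        assert len(pulses) == 1
        p = pulses[0]
        assert abs(p.onset_idx - ramp_start) <= 3
        assert p.peak_force == pytest.approx(40.0)
        assert p.onset_idx == brute_threshold_onset(rec.force, deriv.rfd, p.peak_idx)

    def test_two_pulses_three_seconds_apart(self):
        f1, _ = triangular_pulse()
        f2, _ = triangular_pulse()
        force = np.concatenate([f1, np.zeros(int(3 * FS)), f2])
        rec = make_recording(force)
        pulses = detect_pulses(rec, compute_derivatives(rec))
        assert len(pulses) == 2
        a, b = pulses
        assert a.offset_idx < b.onset_idx  # non-overlapping spans

    def test_low_peaks_rejected(self):
        force, _ = triangular_pulse(peak=8.0)
        rec = make_recording(force)
        assert detect_pulses(rec, compute_derivatives(rec)) == []

    def test_pulse_invariants(self):
        force, _ = triangular_pulse()
        rec = make_recording(force)
        (p,) = detect_pulses(rec, compute_derivatives(rec))
        assert p.onset_idx < p.peak_idx <= p.offset_idx
        assert 0 < p.t_f90 <= p.t_pf


class TestTimeToF90:
    def test_linear_rise_hits_f90_at_180ms(self):
        # 0 -> 40 %MVC over 0.2 s: first sample >= 36 %MVC is at 0.180 s
        force, nb = triangular_pulse(peak=40.0, rise_s=0.2)
        rec = make_recording(force)
        peak_idx = nb + int(0.2 * FS)
        pulse = Pulse(nb, peak_idx, peak_idx + 10, 40.0, 0.2, 0.0)
        assert time_to_f90(rec, pulse) == pytest.approx(0.180)

    def test_single_sample_step(self):
        force = np.concatenate([np.zeros(300), [40.0], np.zeros(300)])
        rec = make_recording(force)
        pulse = Pulse(299, 300, 301, 40.0, 1 / FS, 0.0)
        assert time_to_f90(rec, pulse) == pytest.approx(1 / FS)

    def test_f90_reached_only_at_peak(self):
        # force stays below 90% until the peak sample itself
        rise = np.concatenate([np.linspace(0, 30, 40), [40.0]])
        force = np.concatenate([np.zeros(300), rise, np.linspace(40, 0, 60), np.zeros(300)])
        rec = make_recording(force)
        pulse = Pulse(300, 340, 380, 40.0, 40 / FS, 0.0)
        assert time_to_f90(rec, pulse) == pytest.approx(pulse.t_pf)


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([1, 1, -1, -1], 1),
            ([1, 0, 0, -1], 1),  # zeros inherit the previous sign
            ([1, -1, 1, -1, 1, -1], 5),
            ([1, 1, 1], 0),
            ([0, 0, 1, -1], 1),  # leading zeros have no sign
        ],
    )
    def test_counts(self, series, expected):
        n, _ = zero_crossings(np.asarray(series, float), (0, len(series) - 1))
        assert n == expected

    def test_positions_are_first_sample_of_new_sign(self):
        _, pos = zero_crossings(np.array([1.0, 1.0, -2.0, 3.0]), (0, 3))
        assert pos == [2, 3]

    def test_interval_bounds_checked(self):
        with pytest.raises(ValueError):
            zero_crossings(np.ones(5), (0, 7))

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(4, 40))
            x[rng.random(x.size) < 0.1] = 0.0
            n, _ = zero_crossings(x, (0, x.size - 1))
            signs = [s for s in np.sign(x) if s != 0]
            brute = sum(a != b for a, b in zip(signs, signs[1:]))
            assert n == brute


@pytest.mark.parametrize("n_zc,expected", [(0, 1), (1, 1), (2, 2), (5, 3), (9, 5)])
def test_segment_count_formula(n_zc, expected):
    assert segment_count(n_zc) == expected
    import math

    assert segment_count(n_zc) == math.ceil((n_zc + 1) / 2)


class TestExtractBoundaries:
    def test_no_crossings_single_segment(self):
        pulse = Pulse(10, 50, 60, 40.0, 0.2, 0.18)
        segs, slow = extract_boundaries(np.zeros(100), pulse, [])
        assert segs == [(10, 50)] and slow == []

    def test_smooth_single_burst(self):
        _, (p, prof) = analyzed_pulse(burst_train([0.152], []))
        assert len(prof.segments) == 1
        assert prof.slowing_periods == []
        assert prof.segments[0][0] == p.onset_idx

    def test_two_burst_slowing_duration_recovered(self):
        train = burst_train([0.086, 0.065], [0.080])
        _, (p, prof) = analyzed_pulse(train)
        assert prof.n_seg_peak == 2
        assert len(prof.slowing_durations) == 1
        assert prof.slowing_durations[0] == pytest.approx(0.080, abs=0.015)

    @pytest.mark.parametrize("n_bursts", [1, 2, 3, 4])
    def test_tiling_invariant(self, n_bursts):
        durs = [0.086, 0.065, 0.052, 0.054][:n_bursts]
        gaps = [0.080, 0.060, 0.050][: n_bursts - 1]
        _, (p, prof) = analyzed_pulse(burst_train(durs, gaps))
        segs, slow = prof.segments, prof.slowing_periods
        assert len(slow) == len(segs) - 1
        # interleaved, disjoint, ordered, jointly tiling first start..last end
        cursor = segs[0][0]
        for k, seg in enumerate(segs):
            assert seg[0] == cursor
            assert seg[1] >= seg[0]
            if k < len(slow):
                assert slow[k][0] == seg[1]
                assert slow[k][1] >= slow[k][0]
                cursor = slow[k][1]
        assert segs[-1][1] >= segs[-1][0]


class TestPulseMetrics:
    def test_linear_ramp_metrics(self):
        force, _ = triangular_pulse(peak=40.0, rise_s=0.2)
        rec = make_recording(force)
        deriv = compute_derivatives(rec)
        (p,) = detect_pulses(rec, deriv)
        prof = segment_pulse(rec, deriv, p)
        assert prof.rfd_pk == pytest.approx(200.0, rel=0.02)
        assert prof.seg_of_rfd_pk == 1
        assert prof.rfd_pk_seg1 == prof.rfd_pk

    def test_single_segment_first_equals_overall(self):
        _, (p, prof) = analyzed_pulse(burst_train([0.152], []))
        assert prof.n_seg_peak == 1
        assert prof.rfd_pk_seg1 == prof.rfd_pk

    def test_stronger_second_burst_hosts_peak_rfd(self):
        # fully silent gap isolates the amplitude effect on per-segment RFD
        train = burst_train([0.086, 0.065], [0.080], amps=(1.0, 1.5))
        _, (p, prof) = analyzed_pulse(train, gap_drive_frac=0.0)
        assert prof.seg_of_rfd_pk == 2
        assert prof.rfd_pk_seg1 < prof.rfd_pk

    def test_metric_invariants_on_noisy_pulses(self, rng):
        for seed in range(20):
            train = burst_train([0.086, 0.065, 0.052][: int(rng.integers(1, 4))], [0.080, 0.060])
            _, (p, prof) = analyzed_pulse(train, noise_sd=0.3, seed=seed)
            assert prof.n_seg_f90 <= prof.n_seg_peak
            assert prof.rfd_pk_seg1 <= prof.rfd_pk
            assert 1 <= prof.seg_of_rfd_pk <= prof.n_seg_peak
            total = sum(prof.segment_durations) + sum(prof.slowing_durations)
            assert total <= p.t_pf + 2 / FS
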