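"""Pulse detection and force-segment analysis.

A rapid force pulse is delimited by a rate-of-force-development threshold
(default 20 %MVC/s): the onset is the first sample after the last
sub-threshold RFD sample scanning backward from the pulse's force peak, and
the offset is found symmetrically on the relaxation side.

Within a pulse, segments of active force rise are delimited by the zero
crossings of F''(t): the number of segments on an interval is
``ceil((zero crossings + 1) / 2)``.  A segment ends at the F'' minimum
between a falling and the next rising crossing; segments after the first
begin at the F'' maximum between a rising and the next falling crossing
(the first segment begins at force initiation).  The plateaus between
consecutive segments are the slowing periods — the transient reductions in
neuromuscular drive that define motor segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .kinematics import DerivativeSet
from .recording_io import ForceRecording, MalformedInputError

__all__ = [
    "Pulse",
    "SegmentationProfile",
    "QCFlag",
    "detect_pulses",
    "time_to_f90",
    "zero_crossings",
    "segment_count",
    "extract_boundaries",
    "pulse_metrics",
    "segment_pulse",
]

#: QC reasons a pulse can be flagged with.
QC_REASONS = ("amplitude_out_of_range", "merged_pulses", "onset_ambiguity")


@dataclass(frozen=True)
class QCFlag:
    """Programmatic quality flag, optionally overridden from a manual file."""

    reason: str
    override: str | None = None  # "keep" | "drop" | None

    def __post_init__(self) -> None:
        if self.reason not in QC_REASONS:
            raise ValueError(f"unknown QC reason {self.reason!r}")
        if self.override not in (None, "keep", "drop"):
            raise ValueError(f"override must be keep/drop, got {self.override!r}")


@dataclass
class Pulse:
    """One detected force pulse (indices into the source recording)."""

    onset_idx: int
    peak_idx: int
    offset_idx: int
    peak_force: float  # %MVC
    t_pf: float  # s, onset -> peak
    t_f90: float  # s, onset -> first sample >= 90% of peak force
    qc_flags: list[QCFlag] = field(default_factory=list)

    @property
    def dropped(self) -> bool:
        """True when any flag drops the pulse and no manual override keeps it."""
        if any(f.override == "keep" for f in self.qc_flags):
            return False
        return any(f.override == "drop" for f in self.qc_flags) or any(
            f.override is None and f.reason in ("merged_pulses",) for f in self.qc_flags
        )


@dataclass
class SegmentationProfile:
    """Segment structure and rate metrics of one pulse."""

    zc_to_f90: int
    zc_to_peak: int
    n_seg_f90: int
    n_seg_peak: int
    segments: list[tuple[int, int]]
    slowing_periods: list[tuple[int, int]]
    segment_durations: list[float]  # s
    slowing_durations: list[float]  # s
    first_seg_dur: float  # s
    rfd_pk: float  # %MVC/s
    t_rfd_pk: float  # s from onset
    rfd_pk_seg1: float  # %MVC/s
    seg_of_rfd_pk: int


def detect_pulses(
    rec: ForceRecording,
    deriv: DerivativeSet,
    rfd_threshold: float = 20.0,
    min_peak: float = 10.0,
    min_separation: float = 1.0,
    baseline_frac: float = 0.05,
) -> list[Pulse]:
    """Detect rapid force pulses in a normalized recording.

    Candidate peaks are local force maxima of at least ``min_peak`` %MVC
    separated by at least ``min_separation`` seconds.  The onset is the
    sample immediately after the last baseline sample scanning backward
    from the peak, where baseline means RFD below ``rfd_threshold`` with
    force back in the baseline band (below ``baseline_frac`` of the peak);
    the force condition keeps the scan bridging the slowing periods of a
    segmented rise, where RFD dips sub-threshold while force stays
    elevated, without chaining across baseline noise.  The offset is the
    sample immediately before RFD first returns above ``-rfd_threshold``
    after having dropped below it during relaxation.

    Pulses whose onset or offset search collides with a neighboring pulse
    are flagged ``merged_pulses``; pulses whose backward scan finds no
    suprathreshold RFD excursion are flagged ``onset_ambiguity``.
    """
    if not rec.normalized:
        raise MalformedInputError("pulse detection requires a normalized recording")
    if deriv.source_length != rec.force.size:
        raise ValueError("derivative set does not match the recording")
    force, rfd = rec.force, deriv.rfd
    fs = rec.sample_rate
    distance = max(1, int(round(min_separation * fs)))
    peaks, _ = find_peaks(force, height=min_peak, distance=distance)

    pulses: list[Pulse] = []
    for j, pk in enumerate(peaks):
        flags: list[QCFlag] = []
        prev_pk = peaks[j - 1] if j > 0 else None
        next_pk = peaks[j + 1] if j + 1 < len(peaks) else None

        lo = 0 if prev_pk is None else int(prev_pk)
        f_base = baseline_frac * force[pk]
        i = int(pk)
        while i > lo and (rfd[i - 1] >= rfd_threshold or force[i - 1] >= f_base):
            i -= 1
        onset = i
        if onset == lo:
            flags.append(
                QCFlag("merged_pulses" if prev_pk is not None else "onset_ambiguity")
            )
        elif not np.any(rfd[onset : int(pk) + 1] >= rfd_threshold):
            flags.append(QCFlag("onset_ambiguity"))

        # Offset: scan forward; after RFD has dropped below -threshold, the
        # sample immediately before the first sample with RFD > -threshold.
        hi = force.size - 1 if next_pk is None else int(next_pk)
        i = int(pk)
        while i < hi and rfd[i] > -rfd_threshold:
            i += 1
        below = i
        if below >= hi and rfd[min(below, hi)] > -rfd_threshold:
            offset = hi
            if next_pk is not None:
                flags.append(QCFlag("merged_pulses"))
        else:
            i = below
            while i < hi and rfd[i] <= -rfd_threshold:
                i += 1
            offset = i - 1 if (i < hi or rfd[i] > -rfd_threshold) else i
            if offset >= hi and next_pk is not None:
                flags.append(QCFlag("merged_pulses"))

        peak_force = float(force[pk])
        if onset >= pk:
            # degenerate: threshold crossed at the peak itself
            onset = max(pk - 1, 0)
        f90_idx = _f90_index(force, onset, int(pk))
        pulses.append(
            Pulse(
                onset_idx=int(onset),
                peak_idx=int(pk),
                offset_idx=int(max(offset, pk)),
                peak_force=peak_force,
                t_pf=(int(pk) - int(onset)) / fs,
                t_f90=(f90_idx - int(onset)) / fs,
                qc_flags=flags,
            )
        )
    return pulses


def _f90_index(force: np.ndarray, onset: int, peak: int) -> int:
    target = 0.9 * force[peak]
    rel = np.nonzero(force[onset : peak + 1] >= target)[0]
    return onset + int(rel[0])  # peak always qualifies


def time_to_f90(rec: ForceRecording, pulse: Pulse) -> float:
    """Seconds from force initiation to the first sample >= 90% of peak force.

    No interpolation: the first qualifying sample is taken, so the value is a
    multiple of the sample interval.
    """
    j = _f90_index(rec.force, pulse.onset_idx, pulse.peak_idx)
    return (j - pulse.onset_idx) / rec.sample_rate


def zero_crossings(f2, interval: tuple[int, int]) -> tuple[int, list[int]]:
    """Count strict sign changes of F'' on the inclusive interval ``[a, b]``.

    Samples that are exactly zero inherit the previous non-zero sign, so a
    plateau touching zero is never double-counted.  Each crossing is recorded
    at the index of the first sample of the new sign.
    """
    f2 = np.asarray(f2, dtype=float)
    a, b = interval
    if not (0 <= a < b < f2.size):
        raise ValueError(f"interval [{a}, {b}] outside series of {f2.size} samples")
    prev = 0
    crossings: list[int] = []
    for idx in range(a, b + 1):
        s = int(np.sign(f2[idx]))
        if s == 0:
            continue
        if prev != 0 and s != prev:
            crossings.append(idx)
        prev = s
    return len(crossings), crossings


def segment_count(n_zc: int) -> int:
    """Segments on an interval with ``n_zc`` F'' zero crossings.

    ``ceil((n_zc + 1) / 2)``: one smooth rise gives one crossing and one
    segment; each extra crossing pair adds a segment; an even count means a
    segment is still in progress at the interval's right edge and is counted.
    """
    if n_zc < 0:
        raise ValueError("crossing count must be nonnegative")
    return (n_zc + 2) // 2


def extract_boundaries(
    f2, pulse: Pulse, crossings: list[int]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Segment and slowing-period boundaries from the pre-peak crossings.

    With crossings ``z1 < z2 < ...`` on ``[onset, peak]``: segment 1 runs
    from the onset to the F'' minimum on ``[z1, z2]``; segment k (k >= 2)
    runs from the F'' maximum on ``[z(2k-2), z(2k-1)]`` to the F'' minimum on
    ``[z(2k-1), z(2k)]``.  A final in-progress segment lacking its closing
    crossing pair ends at the peak (and, if its opening pair is incomplete,
    starts at the F'' maximum between the last crossing and the peak).
    Slowing period k spans from the end of segment k to the start of segment
    k+1.  With no crossings the whole rise is a single segment.
    """
    f2 = np.asarray(f2, dtype=float)
    onset, peak = pulse.onset_idx, pulse.peak_idx
    z = list(crossings)
    if not z:
        return [(onset, peak)], []
    n_seg = segment_count(len(z))
    segments: list[tuple[int, int]] = []
    for k in range(1, n_seg + 1):
        if k == 1:
            start = onset
        else:
            i0 = z[2 * k - 3]
            i1 = z[2 * k - 2] if 2 * k - 2 < len(z) else peak
            start = i0 + int(np.argmax(f2[i0 : i1 + 1]))
        if 2 * k - 1 < len(z):
            j0, j1 = z[2 * k - 2], z[2 * k - 1]
            end = j0 + int(np.argmin(f2[j0 : j1 + 1]))
        else:
            end = peak
        segments.append((start, max(start, end)))
    slowing = [
        (segments[i][1], segments[i + 1][0]) for i in range(len(segments) - 1)
    ]
    return segments, slowing


def pulse_metrics(
    rec: ForceRecording,
    deriv: DerivativeSet,
    pulse: Pulse,
    segments: list[tuple[int, int]],
) -> tuple[float, float, float, int]:
    """Peak-RFD metrics: (rfd_pk, t_rfd_pk, rfd_pk_seg1, seg_of_rfd_pk).

    ``rfd_pk`` is the maximum RFD between onset and peak, with its latency
    ``t_rfd_pk`` from onset (earliest index on ties); ``rfd_pk_seg1``
    restricts the maximum to the first segment.  ``seg_of_rfd_pk`` is the
    1-based segment containing the RFD argmax; an argmax falling in a
    slowing period is assigned to the nearer adjacent segment (earlier on an
    exact tie).
    """
    rfd = deriv.rfd
    onset, peak = pulse.onset_idx, pulse.peak_idx
    win = rfd[onset : peak + 1]
    arg = onset + int(np.argmax(win))
    rfd_pk = float(rfd[arg])
    t_rfd_pk = (arg - onset) / rec.sample_rate
    s1a, s1b = segments[0]
    rfd_pk_seg1 = float(np.max(rfd[s1a : s1b + 1]))

    seg_of = None
    for k, (a, b) in enumerate(segments, start=1):
        if a <= arg <= b:
            seg_of = k
            break
    if seg_of is None:
        # argmax fell inside a slowing period: nearer adjacent segment
        best, best_dist = 1, np.inf
        for k, (a, b) in enumerate(segments, start=1):
            dist = min(abs(arg - a), abs(arg - b))
            if dist < best_dist:  # strict: earlier segment wins exact ties
                best, best_dist = k, dist
        seg_of = best
    return rfd_pk, t_rfd_pk, rfd_pk_seg1, seg_of


def segment_pulse(
    rec: ForceRecording, deriv: DerivativeSet, pulse: Pulse
) -> SegmentationProfile:
    """Full segmentation profile for one detected pulse."""
    fs = rec.sample_rate
    onset, peak = pulse.onset_idx, pulse.peak_idx
    f90_idx = _f90_index(rec.force, onset, peak)
    zc_peak, crossings = zero_crossings(deriv.f2, (onset, peak))
    if f90_idx > onset:
        zc_f90, _ = zero_crossings(deriv.f2, (onset, f90_idx))
    else:
        zc_f90 = 0
    segments, slowing = extract_boundaries(deriv.f2, pulse, crossings)
    seg_dur = [(b - a) / fs for a, b in segments]
    slow_dur = [(b - a) / fs for a, b in slowing]
    rfd_pk, t_rfd_pk, rfd_pk_seg1, seg_of = pulse_metrics(rec, deriv, pulse, segments)
    return SegmentationProfile(
        zc_to_f90=zc_f90,
        zc_to_peak=zc_peak,
        n_seg_f90=segment_count(zc_f90),
        n_seg_peak=segment_count(zc_peak),
        segments=segments,
        slowing_periods=slowing,
        segment_durations=seg_dur,
        slowing_durations=slow_dur,
        first_seg_dur=seg_dur[0],
        rfd_pk=rfd_pk,
        t_rfd_pk=t_rfd_pk,
        rfd_pk_seg1=rfd_pk_seg1,
        seg_of_rfd_pk=seg_of,
    )
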