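"""Synthetic burst-drive force simulator.

Rapid isometric force pulses are generated from a simple excitation model:
neuromuscular drive is a train of rectangular bursts, force is the drive
convolved with a critically damped second-order twitch kernel
``h(t) = (t / tau^2) exp(-t / tau)`` (unit steady-state gain), scaled so the
noiseless peak hits a drawn target amplitude.  Sessions emulate the
acquisition chain of the force protocol: 50 Hz forward-backward low-pass,
200 Hz sampling, broadband Gaussian noise added after filtering, and cue
spacing of 3-5 s between pulses.

Single-burst pulses produce the smooth rise typical of healthy older adults
(OA) and of Parkinson's subjects without segmentation; multi-burst pulses
with short bursts separated by drive gaps produce the segmented force
profiles of PD_Seg, with the generative gap durations appearing as slowing
periods in the analyzed force.  Every emitted pulse carries a ground-truth
record (burst count, boundaries, intended peak) so recovery can be scored
without re-parsing output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .recording_io import ForceRecording

__all__ = [
    "ARCHETYPES",
    "BurstTrain",
    "SimConfig",
    "PulseTruth",
    "GroundTruth",
    "simulate_pulse",
    "simulate_session",
    "simulate_cohort",
    "write_cohort",
]

ARCHETYPES = ("OA", "PD_NoSeg", "PD_Seg")

#: Mean segment (burst) durations in seconds by ordinal position for
#: multi-burst pulses, and the slowing-period (gap) means between them.
MULTI_BURST_DUR_MEANS = (0.086, 0.065, 0.0525, 0.0537, 0.0525)
MULTI_BURST_DUR_CVS = (0.255, 0.185, 0.161, 0.206, 0.163)
GAP_MEANS = (0.080, 0.0597, 0.0505, 0.049, 0.0501)
GAP_CVS = (0.199, 0.216, 0.220, 0.187, 0.163)

#: Relative drive amplitude by burst ordinal.  The profile escalates so the
#: force maximum falls in the final burst (each burst must push force past
#: the partially decayed contribution of its predecessors); the jump from
#: the first to the second burst is the largest, so the peak RFD of a
#: typical segmented (2-3 burst) pulse falls in the second segment.
BURST_AMP_PROFILE = (1.0, 1.35, 1.55, 1.75, 1.95)

#: Single-burst drive duration means (s): the uninterrupted rise of a
#: non-segmented pulse lasts on the order of 150-165 ms.
SINGLE_BURST_DUR_MEAN = {"OA": 0.152, "PD_NoSeg": 0.165, "PD_Seg": 0.16}
SINGLE_BURST_DUR_CV = 0.15

#: Probability that a pulse is multi-burst, per archetype, and the burst
#: count mixture for multi-burst pulses.
P_MULTI = {"OA": 0.042, "PD_NoSeg": 0.274, "PD_Seg": 0.82}
MULTI_COUNT_P = {
    "OA": {2: 1.0},
    "PD_NoSeg": {2: 0.8, 3: 0.2},
    "PD_Seg": {2: 0.45, 3: 0.30, 4: 0.15, 5: 0.10},
}


@dataclass(frozen=True)
class BurstTrain:
    """Drive-level description of one pulse: ordered non-overlapping bursts."""

    onsets: tuple[float, ...]  # s from pulse start
    durations: tuple[float, ...]  # s
    amplitudes: tuple[float, ...]  # drive units
    target_peak: float  # %MVC

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.durations) or len(self.onsets) != len(self.amplitudes):
            raise ValueError("onsets, durations, amplitudes must align")
        if any(d <= 0 for d in self.durations):
            raise ValueError("burst durations must be positive")
        ends = np.array(self.onsets) + np.array(self.durations)
        if np.any(np.array(self.onsets)[1:] < ends[:-1]):
            raise ValueError("bursts must be ordered and non-overlapping")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults mirror the acquisition and cohort characteristics the pipeline
    is designed for: 200 Hz sampling with 50 Hz low-pass character, pulses
    cued 3-5 s apart, peak amplitudes near 40 %MVC (SD 3.5), multi-burst
    segment/gap durations around 86/65/52 ms and 80/60/50 ms.
    """

    sample_rate: float = 200.0
    lowpass_hz: float = 50.0
    twitch_tau: float = 0.025  # s; calibrates peak RFD of a smooth pulse
    gap_drive_frac: float = 0.6  # residual drive during slowing periods
    noise_sd: float = 0.3  # %MVC, added after filtering
    ipi_range: tuple[float, float] = (3.0, 5.0)  # s between pulse onsets
    n_pulses: int = 45
    archetype: str = "OA"
    peak_mean: float = 40.0  # %MVC
    peak_sd: float = 3.5
    mvc_mean: float = 45.0  # N, per-subject MVC draw
    mvc_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"archetype must be one of {ARCHETYPES}, got {self.archetype!r}")
        if self.sample_rate <= 0 or self.twitch_tau <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class PulseTruth:
    """Ground truth for one emitted pulse."""

    pulse_index: int
    onset_time: float  # s, drive onset within the session
    n_bursts: int
    burst_onsets: tuple[float, ...]  # s relative to drive onset
    burst_durations: tuple[float, ...]
    gap_durations: tuple[float, ...]
    target_peak: float  # %MVC


@dataclass
class GroundTruth:
    """Sidecar truth for a session or cohort, keyed by (subject, pulse)."""

    subject_id: str
    archetype: str
    pulses: list[PulseTruth] = field(default_factory=list)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at +/- 3 SD (and strictly positive)."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 3 * sd and x > 0:
            return float(x)
    return float(mean)


def _draw_burst_train(config: SimConfig, rng: np.random.Generator) -> BurstTrain:
    arch = config.archetype
    if rng.random() < P_MULTI[arch]:
        counts, probs = zip(*sorted(MULTI_COUNT_P[arch].items()))
        n_bursts = int(rng.choice(counts, p=probs))
    else:
        n_bursts = 1
    target = _truncnorm(rng, config.peak_mean, config.peak_sd)
    if n_bursts == 1:
        dur = _truncnorm(rng, SINGLE_BURST_DUR_MEAN[arch], SINGLE_BURST_DUR_MEAN[arch] * SINGLE_BURST_DUR_CV)
        return BurstTrain(onsets=(0.0,), durations=(dur,), amplitudes=(1.0,), target_peak=target)
    onsets, durs, amps = [], [], []
    t = 0.0
    for j in range(n_bursts):
        mean_d = MULTI_BURST_DUR_MEANS[min(j, len(MULTI_BURST_DUR_MEANS) - 1)]
        cv_d = MULTI_BURST_DUR_CVS[min(j, len(MULTI_BURST_DUR_CVS) - 1)]
        d = _truncnorm(rng, mean_d, mean_d * cv_d)
        onsets.append(t)
        durs.append(d)
        # amplitude divided by the kernel's finite-burst response so each
        # burst's standalone force bump follows the escalating profile
        # irrespective of its sampled duration
        x = d / config.twitch_tau
        resp = 1.0 - (1.0 + x) * np.exp(-x)
        amps.append(
            BURST_AMP_PROFILE[min(j, len(BURST_AMP_PROFILE) - 1)]
            / resp
            * _truncnorm(rng, 1.0, 0.05)
        )
        t += d
        if j < n_bursts - 1:
            mean_g = GAP_MEANS[min(j, len(GAP_MEANS) - 1)]
            cv_g = GAP_CVS[min(j, len(GAP_CVS) - 1)]
            t += _truncnorm(rng, mean_g, mean_g * cv_g)
    return BurstTrain(
        onsets=tuple(onsets), durations=tuple(durs), amplitudes=tuple(amps), target_peak=target
    )


def _twitch_kernel(config: SimConfig) -> np.ndarray:
    dt = 1.0 / config.sample_rate
    t = np.arange(0.0, 10.0 * config.twitch_tau, dt)
    h = t / config.twitch_tau**2 * np.exp(-t / config.twitch_tau)
    return h * dt  # unit steady-state gain (discrete integral ~ 1)


def _drive_samples(train: BurstTrain, config: SimConfig, n: int) -> np.ndarray:
    """Rectangular burst train plus a residual holding drive during gaps.

    During a slowing period the drive drops to ``gap_drive_frac`` of the
    level that would hold the force reached by the preceding burst, so the
    force plateaus (with a shallow sag) between bursts instead of collapsing
    — the transient reduction, not abolition, of neuromuscular drive that a
    segmented rise reflects.
    """
    fs = config.sample_rate
    drive = np.zeros(n)
    ends = []
    for on, dur, amp in zip(train.onsets, train.durations, train.amplitudes):
        a = int(round(on * fs))
        b = int(round((on + dur) * fs))
        drive[a : max(b, a + 1)] += amp
        ends.append((b, dur, amp))
    for k in range(len(ends) - 1):
        b, dur, amp = ends[k]
        nxt = int(round(train.onsets[k + 1] * fs))
        if nxt > b:
            x = dur / config.twitch_tau
            held = amp * (1.0 - (1.0 + x) * np.exp(-x))  # force level at burst end
            drive[b:nxt] += config.gap_drive_frac * held
    return drive


def simulate_pulse(
    config: SimConfig, rng: np.random.Generator, train: BurstTrain | None = None
) -> tuple[np.ndarray, BurstTrain]:
    """Simulate one pulse; returns (%MVC force samples, burst train used).

    The returned window covers the drive plus a relaxation tail.  The
    noiseless convolved signal is scaled so its peak equals the train's
    target; the low-pass and additive noise follow, mirroring a recording
    chain in which noise enters after the anti-alias filter.
    """
    if train is None:
        train = _draw_burst_train(config, rng)
    fs = config.sample_rate
    drive_end = train.onsets[-1] + train.durations[-1]
    n = int(round((drive_end + 0.6) * fs))
    drive = _drive_samples(train, config, n)
    kernel = _twitch_kernel(config)
    force = np.convolve(drive, kernel)[:n]
    peak = force.max()
    if peak <= 0:
        raise ValueError("degenerate burst train produced no force")
    force *= train.target_peak / peak
    force = _lowpass(force, config)
    if config.noise_sd > 0:
        force = force + rng.normal(0.0, config.noise_sd, size=n)
    return force, train


def _lowpass(x: np.ndarray, config: SimConfig) -> np.ndarray:
    nyq = config.sample_rate / 2.0
    if config.lowpass_hz >= nyq:
        return x
    b, a = butter(4, config.lowpass_hz / nyq)
    return filtfilt(b, a, x)


def simulate_session(
    config: SimConfig, subject_id: str = "S000"
) -> tuple[ForceRecording, GroundTruth, float]:
    """Simulate one subject session: returns (raw recording, truth, MVC in N).

    Pulses are placed on a quiet baseline with uniform 3-5 s onset spacing;
    the whole session is low-pass filtered once and broadband noise is added
    once, so baseline noise matches the within-pulse noise.  The recording
    is emitted in raw newtons (``force_N = %MVC / 100 * MVC``) so the
    normalization path of the pipeline is exercised.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    truth = GroundTruth(subject_id=subject_id, archetype=config.archetype)
    if config.n_pulses == 0:
        rec = ForceRecording(subject_id=subject_id, sample_rate=fs, force=np.zeros(0))
        return rec, truth, _truncnorm(rng, config.mvc_mean, config.mvc_sd)

    onsets = []
    t = rng.uniform(*config.ipi_range)
    for _ in range(config.n_pulses):
        onsets.append(t)
        t += rng.uniform(*config.ipi_range)
    total = t + 2.0
    n = int(round(total * fs))
    session = np.zeros(n)
    kernel = _twitch_kernel(config)
    for idx, onset in enumerate(onsets):
        train = _draw_burst_train(config, rng)
        drive_end = train.onsets[-1] + train.durations[-1]
        m = int(round((drive_end + 0.6) * fs))
        drive = _drive_samples(train, config, m)
        pulse = np.convolve(drive, kernel)[:m]
        pulse *= train.target_peak / pulse.max()
        a = int(round(onset * fs))
        session[a : a + m] += pulse[: max(0, n - a)]
        gaps = tuple(
            float(train.onsets[j + 1] - (train.onsets[j] + train.durations[j]))
            for j in range(len(train.onsets) - 1)
        )
        truth.pulses.append(
            PulseTruth(
                pulse_index=idx,
                onset_time=float(onset),
                n_bursts=len(train.onsets),
                burst_onsets=train.onsets,
                burst_durations=train.durations,
                gap_durations=gaps,
                target_peak=train.target_peak,
            )
        )
    session = _lowpass(session, config)
    if config.noise_sd > 0:
        session = session + rng.normal(0.0, config.noise_sd, size=n)
    mvc = _truncnorm(rng, config.mvc_mean, config.mvc_sd)
    raw = session / 100.0 * mvc
    rec = ForceRecording(subject_id=subject_id, sample_rate=fs, force=raw)
    return rec, truth, mvc


def simulate_cohort(
    n_seg: int = 39,
    n_noseg: int = 18,
    n_oa: int = 22,
    master_seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[list[ForceRecording], pd.DataFrame, list[GroundTruth]]:
    """Simulate a cohort of subject sessions with known archetypes.

    Default group sizes (39 segmented-like PD, 18 non-segmented-like PD,
    22 OA) mirror the cohort the pipeline targets.  Per-subject seeds are
    derived from the master seed, so the cohort is reproducible and
    independent of processing order.  Returns raw recordings, a metadata
    table (subject_id, group, mvc_n) and the ground-truth sidecars.
    """
    if min(n_seg, n_noseg, n_oa) < 0:
        raise ValueError("group counts must be nonnegative")
    base = config or SimConfig()
    from .subject_aggregation import subject_seed

    recs: list[ForceRecording] = []
    truths: list[GroundTruth] = []
    rows = []
    plan = (
        [("PD_Seg", f"PD{i:03d}") for i in range(n_seg)]
        + [("PD_NoSeg", f"PD{i + n_seg:03d}") for i in range(n_noseg)]
        + [("OA", f"OA{i:03d}") for i in range(n_oa)]
    )
    for arch, sid in plan:
        cfg = replace(base, archetype=arch, seed=subject_seed(master_seed, sid))
        rec, truth, mvc = simulate_session(cfg, subject_id=sid)
        recs.append(rec)
        truths.append(truth)
        rows.append(
            {"subject_id": sid, "group": "OA" if arch == "OA" else "PD", "mvc_n": mvc}
        )
    return recs, pd.DataFrame(rows), truths


def write_cohort(
    out_dir,
    recordings: list[ForceRecording],
    metadata: pd.DataFrame,
    truths: list[GroundTruth],
    config: SimConfig | None = None,
    master_seed: int | None = None,
) -> None:
    """Write a simulated cohort in the CSV formats the loaders read.

    Layout: ``recordings/<subject>.csv`` (time_s, force in N),
    ``subjects.csv``, ``ground_truth_pulses.csv``,
    ``ground_truth_subjects.csv`` and a ``sim_config.json`` echo with the
    resolved seed.
    """
    from .recording_io import save_recording

    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        save_recording(rec, out / "recordings" / f"{rec.subject_id}.csv")
    metadata.to_csv(out / "subjects.csv", index=False, float_format="%.10g")
    pulse_rows = []
    for truth in truths:
        for pt in truth.pulses:
            pulse_rows.append(
                {
                    "subject_id": truth.subject_id,
                    "pulse_index": pt.pulse_index,
                    "onset_time_s": pt.onset_time,
                    "n_bursts": pt.n_bursts,
                    "burst_durations_s": ";".join(f"{d:.6f}" for d in pt.burst_durations),
                    "gap_durations_s": ";".join(f"{d:.6f}" for d in pt.gap_durations),
                    "target_peak_pct_mvc": pt.target_peak,
                }
            )
    pd.DataFrame(pulse_rows).to_csv(out / "ground_truth_pulses.csv", index=False)
    pd.DataFrame(
        [{"subject_id": t.subject_id, "archetype": t.archetype} for t in truths]
    ).to_csv(out / "ground_truth_subjects.csv", index=False)
    echo = {"master_seed": master_seed}
    if config is not None:
        echo.update({k: getattr(config, k) for k in SimConfig.__dataclass_fields__})
    (out / "sim_config.json").write_text(json.dumps(echo, indent=2, default=str))
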