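import numpy as np
import pytest

from motorseg.kinematics import compute_derivatives
from motorseg.recording_io import ForceRecording
from motorseg.synthetic_cohort import BurstTrain, SimConfig, simulate_pulse

FS = 200.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(force, fs=FS, normalized=True, subject_id="T"):
    return ForceRecording(
        subject_id=subject_id, sample_rate=fs, force=np.asarray(force, float), normalized=normalized
    )


def triangular_pulse(peak=40.0, rise_s=0.2, fall_s=0.3, baseline_s=1.5, fs=FS):
    """Baseline, linear rise to peak, linear fall, baseline."""
    nb = int(baseline_s * fs)
    nr = int(rise_s * fs)
    nf = int(fall_s * fs)
    rise = np.linspace(0.0, peak, nr + 1)
    fall = np.linspace(peak, 0.0, nf + 1)[1:]
    return np.concatenate([np.zeros(nb), rise, fall, np.zeros(nb)]), nb


def burst_train(durations, gaps, amps=None, target=40.0):
    """BurstTrain from duration/gap lists."""
    onsets = [0.0]
    for d, g in zip(durations[:-1], gaps):
        onsets.append(onsets[-1] + d + g)
    amps = amps or tuple(1.0 + 0.35 * i for i in range(len(durations)))
    return BurstTrain(
        onsets=tuple(onsets),
        durations=tuple(durations),
        amplitudes=tuple(amps),
        target_peak=target,
    )


def analyzed_pulse(train, noise_sd=0.0, seed=0, pad_s=2.0, tau=0.025, **cfg_kwargs):
    """Simulate one padded pulse and run detection + segmentation on it."""
    from motorseg.pipeline import analyze_recording

    cfg = SimConfig(noise_sd=noise_sd, twitch_tau=tau, **cfg_kwargs)
    rng = np.random.default_rng(seed)
    f, _ = simulate_pulse(cfg, rng, train)
    pad = rng.normal(0.0, noise_sd, int(pad_s * FS)) if noise_sd > 0 else np.zeros(int(pad_s * FS))
    pad2 = rng.normal(0.0, noise_sd, int(pad_s * FS)) if noise_sd > 0 else np.zeros(int(pad_s * FS))
    rec = make_recording(np.concatenate([pad, f, pad2]))
    out = analyze_recording(rec)
    assert len(out) == 1, f"expected one pulse, found {len(out)}"
    return rec, out[0]


@pytest.fixture(scope="session")
def deriv_factory():
    def _make(force, fs=FS):
        rec = ForceRecording("T", fs, np.asarray(force, float), normalized=True)
        return rec, compute_derivatives(rec)

    return _make
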