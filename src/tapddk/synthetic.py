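"""Synthetic paired-device recordings with known ground truth.

Emulates the study geometry every analysis module is validated against: a
single latent tapping (or syllable) schedule observed simultaneously by a
"smartphone" channel (30 fps 2D video landmarks; phone microphone) and a
"gold standard" channel (60 Hz 3D electromagnetic sensors; reference
microphone).  Inter-event intervals are log-normal around 1/f(t) — the
log-normal keeps durations positive at high jitter CV — with
f(t) = base frequency + slope · t, so that the true mean frequency, rhythm
variability (COV, IIV) and decrement (slope) are known exactly and a
ground-truth :class:`~tapddk.kinematics.FeatureSet` can be computed from
the latent schedule itself.

Default magnitudes follow the study cohort: tapping frequencies centred
near 2.5 Hz and syllable rates near 3 Hz, 10 s recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .config import RunConfig
from .errors import StreamValidationError
from .kinematics import (EventSeries, FeatureSet, LandmarkStream,
                         SensorStream, analyze_tapping, features_from_events)
from .speech import AudioWaveform, analyze_speech
from .agreement import PairedFeatureTable

TAP_TESTS = ("big_fast", "dual_task", "sequence")
DDK_TESTS = ("papapa", "pataka")


@dataclass
class TapSimParams:
    """Latent tapping process and its two observation channels."""

    base_frequency: float = 2.55       # Hz (cohort mean tapping rate)
    duration: float = 10.0             # seconds (protocol length)
    freq_slope: float = 0.0            # Hz/s, true decrement on speed
    interval_jitter_cv: float = 0.05   # CV of inter-tap intervals
    amplitude_px: float = 120.0        # video aperture amplitude, pixels
    amplitude_units: float = 8.0       # sensor aperture amplitude, device units
    position_noise_sd_video: float = 0.01   # fraction of amplitude
    position_noise_sd_sensor: float = 0.005  # fraction of amplitude
    video_fps: float = 30.0
    sensor_rate: float = 60.0
    dropped_frame_prob: float = 0.0    # video only; sensors never drop
    test_label: str = "big_fast"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.base_frequency < 8:
            raise StreamValidationError("base_frequency must be in (0.5, 8) Hz")
        if self.duration <= 1:
            raise StreamValidationError("duration must be > 1 s")
        if self.video_fps < 15:
            raise StreamValidationError("video_fps must be >= 15")
        if self.sensor_rate < 30:
            raise StreamValidationError("sensor_rate must be >= 30")
        if self.interval_jitter_cv < 0:
            raise StreamValidationError("interval_jitter_cv must be >= 0")
        if not 0 <= self.dropped_frame_prob < 1:
            raise StreamValidationError("dropped_frame_prob must be in [0, 1)")


@dataclass
class DDKSimParams:
    """Latent syllable schedule and its two audio channels."""

    syllable_rate: float = 3.0         # Hz (cohort mean speaking rate)
    duration: float = 10.0             # seconds
    rate_slope: float = 0.0            # Hz/s
    interval_jitter_cv: float = 0.05
    burst_duration: float = 0.12       # seconds per syllable burst
    signal_amplitude: float = 0.3      # peak burst amplitude (0 = silence limit)
    snr_db: float = 20.0               # reference-channel SNR
    phone_snr_penalty_db: float = 5.0  # phone channel: snr_db − penalty
    sample_rate: int = 22050
    test_label: str = "papapa"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 < self.syllable_rate < 10:
            raise StreamValidationError("syllable_rate must be in (1, 10) Hz")
        if self.duration < 0.5:  # shortest legal AudioWaveform
            raise StreamValidationError("duration must be >= 0.5 s")
        if not 0 < self.burst_duration < 1.0 / self.syllable_rate:
            raise StreamValidationError(
                "burst_duration must be in (0, 1/syllable_rate)"
            )
        if self.interval_jitter_cv < 0:
            raise StreamValidationError("interval_jitter_cv must be >= 0")
        if self.sample_rate <= 0:
            raise StreamValidationError("sample_rate must be > 0")


# ---------------------------------------------------------------------------
# latent schedule
# ---------------------------------------------------------------------------

def _latent_schedule(rng: np.random.Generator, base: float, slope: float,
                     cv: float, duration: float, t0: float = 0.2) -> np.ndarray:
    """Event times with log-normal inter-event intervals around 1/f(t)."""
    sigma = np.sqrt(np.log1p(cv ** 2))
    times = [t0]
    while True:
        f_now = max(base + slope * times[-1], 0.2)
        mean_int = 1.0 / f_now
        if cv > 0:
            mu = np.log(mean_int) - sigma ** 2 / 2.0
            step = float(rng.lognormal(mu, sigma))
        else:
            step = mean_int
        t_next = times[-1] + step
        if t_next > duration - 0.05:
            break
        times.append(t_next)
    return np.array(times)


def _aperture(t_grid: np.ndarray, events: np.ndarray, amplitude: float) -> np.ndarray:
    """Raised-cosine aperture with full opening at each latent event.

    Between events k and k+1 the phase runs 0 → 2π and the aperture is
    amplitude·(1 + cos φ)/2, so every event is an aperture peak and the
    observable peak-to-peak intervals equal the latent intervals (placing
    peaks mid-interval instead would average adjacent intervals and bias
    rhythm features low).  Outside the schedule, the nearest half-cycle
    tapers to closed.
    """
    a = np.zeros_like(t_grid)
    if len(events) < 2:
        return a
    idx = np.searchsorted(events, t_grid, side="right") - 1
    inside = (idx >= 0) & (idx < len(events) - 1)
    k = idx[inside]
    phase = 2 * np.pi * (t_grid[inside] - events[k]) / (events[k + 1] - events[k])
    a[inside] = amplitude * (1 + np.cos(phase)) / 2.0

    d_first = events[1] - events[0]
    lead = (t_grid < events[0]) & (t_grid >= events[0] - d_first / 2)
    a[lead] = amplitude * (1 + np.cos(
        2 * np.pi * (t_grid[lead] - events[0]) / d_first)) / 2.0
    d_last = events[-1] - events[-2]
    tail = (t_grid >= events[-1]) & (t_grid <= events[-1] + d_last / 2)
    a[tail] = amplitude * (1 + np.cos(
        2 * np.pi * (t_grid[tail] - events[-1]) / d_last)) / 2.0
    return a


def _truth_features(events: np.ndarray, duration: float, test_label: str) -> FeatureSet:
    series = EventSeries(events, np.ones_like(events), duration)
    return features_from_events(series, source="latent", test_label=test_label)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_tap_pair(
    params: TapSimParams,
) -> tuple[LandmarkStream, SensorStream, FeatureSet]:
    """One latent tap schedule observed as paired video + sensor streams."""
    rng = np.random.default_rng(params.seed)
    events = _latent_schedule(rng, params.base_frequency, params.freq_slope,
                              params.interval_jitter_cv, params.duration)

    # video channel: fixed thumb, index moving along x, pixel noise, drops
    n_frames = int(round(params.duration * params.video_fps))
    t_video = np.arange(n_frames) / params.video_fps
    ap = _aperture(t_video, events, params.amplitude_px)
    thumb = np.tile([240.0, 320.0], (n_frames, 1))
    index = thumb + np.column_stack([ap, np.zeros(n_frames)])
    noise_sd = params.position_noise_sd_video * params.amplitude_px
    if noise_sd > 0:
        index = index + rng.normal(0, noise_sd, index.shape)
        thumb = thumb + rng.normal(0, noise_sd, thumb.shape)
    if params.dropped_frame_prob > 0:
        keep = rng.random(n_frames) >= params.dropped_frame_prob
        keep[0] = keep[-1] = True  # keep endpoints so duration is preserved
    else:
        keep = np.ones(n_frames, dtype=bool)
    video = LandmarkStream(t_video[keep], index[keep], thumb[keep],
                           fps=params.video_fps, test_label=params.test_label,
                           device_label="synthetic-phone")

    # sensor channel: 3D, thumb sensor fixed at origin
    n_samp = int(round(params.duration * params.sensor_rate))
    t_sens = np.arange(n_samp) / params.sensor_rate
    ap3 = _aperture(t_sens, events, params.amplitude_units)
    b = np.zeros((n_samp, 3))
    a = np.column_stack([ap3, np.zeros(n_samp), np.zeros(n_samp)])
    sens_sd = params.position_noise_sd_sensor * params.amplitude_units
    if sens_sd > 0:
        a = a + rng.normal(0, sens_sd, a.shape)
        b = b + rng.normal(0, sens_sd, b.shape)
    sensor = SensorStream(t_sens, a, b, sample_rate=params.sensor_rate,
                          test_label=params.test_label, device_label="gold")

    truth = _truth_features(events, params.duration, params.test_label)
    return video, sensor, truth


def _syllable_burst(rng: np.random.Generator, sr: int, dur: float) -> np.ndarray:
    """Band-limited noise burst with a sharp attack and damped decay."""
    n = max(8, int(round(dur * sr)))
    noise = rng.standard_normal(n)
    sos = sp_signal.butter(4, [300, min(3000, sr / 2 - 1)], "bandpass",
                           fs=sr, output="sos")
    carrier = sp_signal.sosfilt(sos, noise)
    attack = max(2, n // 10)
    env = np.ones(n)
    env[:attack] = np.hanning(2 * attack)[:attack]          # fast rise
    env *= np.exp(-np.arange(n) / (0.35 * n))               # damped decay
    env *= np.hanning(2 * n)[n:] * 0.5 + 0.5                # taper the tail
    burst = carrier * env
    peak = np.max(np.abs(burst))
    return burst / peak if peak > 0 else burst


def simulate_ddk_pair(
    params: DDKSimParams,
) -> tuple[AudioWaveform, AudioWaveform, FeatureSet]:
    """One latent syllable schedule as paired phone + reference audio.

    The phone channel receives a lower SNR and a 300 Hz–8 kHz band-pass
    coloration (typical phone microphone response); the reference channel
    is flat at the stated SNR.  Noise is scaled from the clean-signal RMS,
    so a zero signal amplitude is the literal silence limit.
    """
    rng = np.random.default_rng(params.seed)
    sr = params.sample_rate
    events = _latent_schedule(rng, params.syllable_rate, params.rate_slope,
                              params.interval_jitter_cv, params.duration)
    n = int(round(params.duration * sr))
    clean = np.zeros(n)
    for ev in events:
        burst = params.signal_amplitude * _syllable_burst(
            rng, sr, params.burst_duration)
        i0 = int(round(ev * sr))
        i1 = min(i0 + len(burst), n)
        clean[i0:i1] += burst[: i1 - i0]

    sig_rms = float(np.sqrt(np.mean(clean ** 2)))

    def channel(snr_db: float, colored: bool) -> AudioWaveform:
        x = clean
        if colored:
            sos = sp_signal.butter(2, [300, min(8000, sr / 2 - 1)], "bandpass",
                                   fs=sr, output="sos")
            x = sp_signal.sosfilt(sos, clean)
        noise_sd = sig_rms / (10 ** (snr_db / 20.0)) if sig_rms > 0 else 0.0
        y = x + rng.normal(0, noise_sd, n)
        return AudioWaveform(np.clip(y, -1, 1), sr,
                             test_label=params.test_label)

    phone = channel(params.snr_db - params.phone_snr_penalty_db, colored=True)
    phone.device_label = "synthetic-phone"
    reference = channel(params.snr_db, colored=False)
    reference.device_label = "gold"

    truth = _truth_features(events, params.duration, params.test_label)
    return phone, reference, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: per-test pair counts of the validation cohort (tap tests 1–3, talk tests 1–2)
DEFAULT_COHORT = {"big_fast": 29, "dual_task": 24, "sequence": 19,
                  "papapa": 29, "pataka": 29}


def simulate_cohort(
    n_pairs: dict[str, int] | None = None,
    seed: int = 0,
    duration: float = 10.0,
    config: RunConfig | None = None,
) -> dict:
    """Simulate a full paired-device cohort and analyze both channels.

    For each recording, per-subject parameters are drawn around the cohort
    statistics (tapping ~ N(2.55, 0.67) Hz, speech ~ N(2.96, 0.47) Hz,
    jitter CV ~ U(0.05, 0.15), mild negative frequency slope), both
    channels are run through the full analysis pipelines, and the results
    are assembled into one :class:`PairedFeatureTable` per feature x test.

    Returns ``{"tables": [...], "records": [...], "truth": [...]}``.
    """
    n_pairs = dict(DEFAULT_COHORT if n_pairs is None else n_pairs)
    for label, n in n_pairs.items():
        if n < 2:
            raise StreamValidationError(f"{label}: n_pairs must be >= 2")
    config = config or RunConfig()
    rng = np.random.default_rng(seed)

    records: list[dict] = []
    truths: list[dict] = []
    values: dict[tuple[str, str], list[list[float]]] = {}

    rec_id = 0
    for label, n in n_pairs.items():
        for _ in range(n):
            rec_seed = int(rng.integers(0, 2 ** 31 - 1))
            jitter = float(rng.uniform(0.05, 0.15))
            slope = float(rng.normal(-0.02, 0.02))
            if label in TAP_TESTS:
                base = float(np.clip(rng.normal(2.55, 0.67), 1.2, 5.0))
                p = TapSimParams(base_frequency=base, duration=duration,
                                 freq_slope=slope, interval_jitter_cv=jitter,
                                 test_label=label, seed=rec_seed)
                video, sensor, truth = simulate_tap_pair(p)
                phone_fs = analyze_tapping(video, config)
                gold_fs = analyze_tapping(sensor, config)
            elif label in DDK_TESTS:
                rate = float(np.clip(rng.normal(2.96, 0.47), 1.5, 5.0))
                p = DDKSimParams(syllable_rate=rate, duration=duration,
                                 rate_slope=slope, interval_jitter_cv=jitter,
                                 test_label=label, seed=rec_seed)
                phone_wav, ref_wav, truth = simulate_ddk_pair(p)
                phone_fs = analyze_speech(phone_wav, config)
                gold_fs = analyze_speech(ref_wav, config)
            else:
                raise StreamValidationError(f"unknown test label: {label!r}")

            rid = f"rec{rec_id:04d}"
            rec_id += 1
            truths.append({"recording_id": rid, "test_label": label,
                           **truth.as_dict()})
            for fs, dev in ((phone_fs, "synthetic-phone"), (gold_fs, "gold")):
                rec = {"recording_id": rid, "device_label": dev,
                       "test_label": label, **fs.as_dict()}
                records.append(rec)
            for feat in FeatureSet.FEATURE_NAMES:
                values.setdefault((feat, label), []).append(
                    [getattr(phone_fs, feat), getattr(gold_fs, feat)]
                )

    tables = [
        PairedFeatureTable(feat, label, np.array(v))
        for (feat, label), v in values.items()
    ]
    return {"tables": tables, "records": records, "truth": truths}
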