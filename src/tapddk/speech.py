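"""Oral diadochokinesis (DDK) audio analysis.

Pipeline for "pa-pa-pa" / "pa-ta-ka" recordings: stationary-noise spectral
gating, a mel-band onset-strength envelope (the strength-versus-time curve,
min-max normalized to [0, 1]), adaptive peak picking of syllable onsets, and
the same four rhythm/speed features as the tapping module with syllable
"durations" defined as inter-onset intervals.

All audio is resampled internally to a single analysis rate (default
22 050 Hz) so hop geometry is uniform across heterogeneous recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal as sp_signal

from .config import RunConfig
from .errors import DegenerateSignalError, StreamValidationError, TooShortError
from .kinematics import EventSeries, FeatureSet, features_from_events, _stage

logger = logging.getLogger(__name__)

_DDK_TEST_LABELS = ("papapa", "pataka")


@dataclass
class AudioWaveform:
    """Mono audio in [-1, 1] at a known sample rate."""

    samples: np.ndarray
    sample_rate: float
    test_label: str = "papapa"
    device_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise StreamValidationError("AudioWaveform.samples must be mono (1-D)")
        if self.sample_rate <= 0:
            raise StreamValidationError("AudioWaveform.sample_rate must be > 0")
        if len(self.samples) < 0.5 * self.sample_rate:
            raise StreamValidationError(
                "AudioWaveform must be at least 0.5 s long"
            )
        amax = np.max(np.abs(self.samples)) if len(self.samples) else 0.0
        if amax > 1.0 + 1e-9:
            logger.warning("samples outside [-1, 1] clipped (peak %.3f)", amax)
            self.samples = np.clip(self.samples, -1.0, 1.0)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class StrengthCurve:
    """Normalized syllable-strength (onset envelope) versus time."""

    frame_times: np.ndarray
    strengths: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.frame_times.shape != self.strengths.shape:
            raise StreamValidationError("frame_times / strengths length mismatch")
        if len(self.frame_times) >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise StreamValidationError("frame_times must be strictly increasing")
        if len(self.strengths) and (
            self.strengths.min() < -1e-9 or self.strengths.max() > 1 + 1e-9
        ):
            raise StreamValidationError("strengths must lie in [0, 1]")


def resample(audio: AudioWaveform, target_sr: int) -> AudioWaveform:
    """Polyphase resampling to ``target_sr`` (identity if already there)."""
    if int(audio.sample_rate) == int(target_sr):
        return audio
    frac = Fraction(int(target_sr), int(audio.sample_rate)).limit_denominator(1000)
    out = sp_signal.resample_poly(audio.samples, frac.numerator, frac.denominator)
    return AudioWaveform(np.clip(out, -1, 1), target_sr, audio.test_label,
                         audio.device_label)


# ---------------------------------------------------------------------------
# spectral-gating denoiser
# ---------------------------------------------------------------------------

def _gate_nperseg(sr: float) -> int:
    # 2048-sample window at 44.1/48 kHz; scaled (power of two) at other rates
    n = 2048 * sr / 44100.0
    return int(2 ** round(np.log2(max(n, 64))))


def denoise(
    audio: AudioWaveform,
    gate_sd: float = 1.5,
    noise_quantile: float = 0.1,
) -> AudioWaveform:
    """Stationary-noise spectral gating.

    Short-time spectra (75% overlap) are compared bin-wise against a noise
    profile estimated from the lowest-energy ``noise_quantile`` of frames;
    magnitude below ``noise mean + gate_sd * noise SD`` is attenuated with a
    soft (spectral-subtraction) mask smoothed over 3 frames x 3 bins.
    Output has the same length and sample rate as the input.
    """
    if gate_sd < 0:
        raise StreamValidationError("gate_sd must be >= 0")
    if not 0 < noise_quantile < 1:
        raise StreamValidationError("noise_quantile must be in (0, 1)")
    sr = audio.sample_rate
    x = audio.samples
    nperseg = _gate_nperseg(sr)
    if len(x) < 2 * nperseg:
        raise TooShortError(
            f"need at least {2 * nperseg} samples for denoising, got {len(x)}"
        )
    hop = nperseg // 4  # 75% overlap

    f, t, S = sp_signal.stft(x, fs=sr, nperseg=nperseg, noverlap=nperseg - hop)
    mag = np.abs(S)
    if mag.max() == 0.0:  # digital silence passes through untouched
        return AudioWaveform(np.zeros_like(x), sr, audio.test_label,
                             audio.device_label)

    frame_energy = (mag ** 2).sum(axis=0)
    n_noise = max(2, int(round(noise_quantile * mag.shape[1])))
    noise_frames = np.argsort(frame_energy)[:n_noise]
    noise_mean = mag[:, noise_frames].mean(axis=1, keepdims=True)
    noise_sd = mag[:, noise_frames].std(axis=1, keepdims=True)
    thresh = noise_mean + gate_sd * noise_sd

    # soft mask: keep the part of the magnitude exceeding the gate
    floor = 0.05
    with np.errstate(divide="ignore", invalid="ignore"):
        mask = (mag - thresh) / np.where(mag > 0, mag, 1.0)
    mask = np.clip(mask, floor, 1.0)
    mask = ndimage.uniform_filter(mask, size=(3, 3), mode="nearest")

    _, y = sp_signal.istft(S * mask, fs=sr, nperseg=nperseg,
                           noverlap=nperseg - hop)
    y = y[: len(x)]
    if len(y) < len(x):
        y = np.pad(y, (0, len(x) - len(y)))
    return AudioWaveform(np.clip(y, -1, 1), sr, audio.test_label,
                         audio.device_label)


# ---------------------------------------------------------------------------
# mel onset-strength envelope
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(sr: float, n_fft: int, n_mels: int, fmin: float = 50.0):
    """Triangular mel filters over the rFFT bins (rows: mels, cols: bins)."""
    fmax = sr / 2.0
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    fb = np.zeros((n_mels, len(bin_freqs)))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / max(mid - lo, 1e-9)
        down = (hi - bin_freqs) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def onset_strength(
    audio: AudioWaveform,
    hop_s: float = 0.010,
    n_mels: int = 40,
) -> StrengthCurve:
    """Strength-versus-time curve from positive mel log-energy flux.

    Half-wave-rectified first difference of log mel-band energies, summed
    over bands at a 10 ms hop, then min-max normalized to [0, 1].  A
    constant signal (silence) has no flux to normalize and raises
    :class:`DegenerateSignalError`.
    """
    sr = audio.sample_rate
    hop = max(1, int(round(hop_s * sr)))
    nperseg = int(2 ** np.ceil(np.log2(0.025 * sr)))  # ~25 ms window
    if len(audio.samples) < 2 * nperseg:
        raise TooShortError("audio too short for onset analysis")

    f, t, S = sp_signal.stft(
        audio.samples, fs=sr, nperseg=nperseg, noverlap=nperseg - hop,
        boundary=None, padded=False,
    )
    power = np.abs(S) ** 2
    fb = _mel_filterbank(sr, nperseg, n_mels)
    mel = fb @ power
    if mel.max() <= 0.0:
        raise DegenerateSignalError(
            "constant onset envelope (silence?): nothing to normalize"
        )
    # 40 dB dynamic-range floor: energy this far below the global maximum
    # (e.g. a gated noise floor) contributes no flux
    amin = mel.max() * 1e-4
    log_mel = np.log(np.maximum(mel, amin))
    flux = np.maximum(np.diff(log_mel, axis=1), 0.0).sum(axis=0)
    flux = np.concatenate([[0.0], flux])

    lo, hi = flux.min(), flux.max()
    if hi - lo <= 1e-12:
        raise DegenerateSignalError(
            "constant onset envelope (silence?): nothing to normalize"
        )
    strengths = (flux - lo) / (hi - lo)
    return StrengthCurve(t, strengths)


def detect_syllables(
    curve: StrengthCurve,
    min_separation: float = 0.1,
    rel_threshold: float = 1.5,
    floor: float = 0.05,
) -> EventSeries:
    """Pick syllable onsets from a strength curve.

    Events are local maxima exceeding an adaptive threshold
    ``rel_threshold * (1 s moving mean + floor)`` and separated by at least
    ``min_separation`` seconds.  An empty series is a legal result.
    """
    t = curve.frame_times
    v = curve.strengths
    if len(t) < 3:
        return EventSeries(np.array([]), np.array([]),
                           float(t[-1] - t[0]) if len(t) else 0.0)
    hop = float(np.median(np.diff(t)))
    win = max(3, int(round(1.0 / hop)))
    local_mean = ndimage.uniform_filter1d(v, size=win, mode="nearest")
    thresh = rel_threshold * (local_mean + floor)

    peaks, _ = sp_signal.find_peaks(v, distance=max(1, int(round(min_separation / hop))))
    peaks = peaks[v[peaks] > thresh[peaks]]
    duration = float(t[-1] - t[0])
    return EventSeries(t[peaks], np.clip(v[peaks], 0, 1), duration)


def analyze_speech(audio: AudioWaveform, config: RunConfig | None = None) -> FeatureSet:
    """Full DDK pipeline: denoise -> onset envelope -> syllable picking -> features.

    Returns M-SF (syllables per second), COV-SF, IIV over inter-onset
    intervals, and DoS, with ``source="audio"``.
    """
    config = config or RunConfig()
    work = _stage("resample", resample, audio, config.audio_sr)
    if config.denoise:
        work = _stage("denoise", denoise, work,
                      gate_sd=config.gate_sd, noise_quantile=config.noise_quantile)
    try:
        curve = _stage("onset_strength", onset_strength, work,
                       hop_s=config.onset_hop_s, n_mels=config.n_mels)
    except DegenerateSignalError:
        # silence: no speech events, features undefined -- not an error here
        logger.warning("degenerate (silent) recording: 0 syllables detected")
        nan = float("nan")
        return FeatureSet(nan, nan, nan, nan, 0, "audio", audio.test_label,
                          defined=False)
    events = _stage("detect_syllables", detect_syllables, curve,
                    min_separation=config.onset_min_separation_s,
                    rel_threshold=config.onset_rel_threshold,
                    floor=config.onset_floor)
    return _stage("features", features_from_events, events,
                  source="audio", test_label=audio.test_label,
                  dos_method=config.dos_method)
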