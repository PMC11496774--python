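"""Finger-tapping kinematics.

Converts keypoint streams (2D video landmarks or 3D wearable-sensor
positions) into an aperture displacement-versus-time curve, segments tap
cycles as peaks of the normalized aperture, and computes four movement
features:

* **M-TF** — mean tapping frequency: tap cycles per second, Hz;
* **COV-TF** — coefficient of variation of the instantaneous tapping
  frequency (rhythm), dimensionless;
* **IIV** — intra-individual variance: variance of tap-cycle durations, s^2;
* **DoS** — decrement on speed: slope of instantaneous frequency over the
  recording, Hz/s (negative = slowing).

The aperture is the index-fingertip-to-thumbtip Euclidean distance per
frame (pixels for video, device length units for sensors); tap cycles
appear as oscillations of this curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .config import RunConfig
from .errors import DegenerateSignalError, StreamValidationError

logger = logging.getLogger(__name__)

_TAP_TEST_LABELS = ("big_fast", "dual_task", "sequence")


def _check_times(timestamps: np.ndarray, owner: str) -> None:
    if timestamps.ndim != 1 or len(timestamps) < 2:
        raise StreamValidationError(f"{owner}.timestamps must be 1-D with length >= 2")
    if not np.all(np.diff(timestamps) > 0):
        raise StreamValidationError(f"{owner}.timestamps must be strictly increasing")


@dataclass
class LandmarkStream:
    """Per-frame 2D pixel positions of index fingertip and thumb tip."""

    timestamps: np.ndarray  # seconds
    index_xy: np.ndarray    # (n, 2) pixels
    thumb_xy: np.ndarray    # (n, 2) pixels
    fps: float = 30.0
    test_label: str = "big_fast"
    device_label: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.index_xy = np.asarray(self.index_xy, dtype=float)
        self.thumb_xy = np.asarray(self.thumb_xy, dtype=float)
        _check_times(self.timestamps, "LandmarkStream")
        n = len(self.timestamps)
        for name in ("index_xy", "thumb_xy"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise StreamValidationError(
                    f"LandmarkStream.{name} has shape {arr.shape}, expected ({n}, 2)"
                )
        if self.fps <= 0:
            raise StreamValidationError("LandmarkStream.fps must be > 0")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class SensorStream:
    """Per-sample 3D positions of two motion sensors (gold standard)."""

    timestamps: np.ndarray       # seconds
    sensor_a_xyz: np.ndarray     # (n, 3) device units, index fingertip
    sensor_b_xyz: np.ndarray     # (n, 3) device units, thumb tip
    sample_rate: float = 60.0
    test_label: str = "big_fast"
    device_label: str = "gold"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.sensor_a_xyz = np.asarray(self.sensor_a_xyz, dtype=float)
        self.sensor_b_xyz = np.asarray(self.sensor_b_xyz, dtype=float)
        _check_times(self.timestamps, "SensorStream")
        n = len(self.timestamps)
        for name in ("sensor_a_xyz", "sensor_b_xyz"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise StreamValidationError(
                    f"SensorStream.{name} has shape {arr.shape}, expected ({n}, 3)"
                )
        if self.sample_rate <= 0:
            raise StreamValidationError("SensorStream.sample_rate must be > 0")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class DisplacementCurve:
    """Aperture (index-thumb distance) versus time."""

    timestamps: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_times(self.timestamps, "DisplacementCurve")
        if self.values.shape != self.timestamps.shape:
            raise StreamValidationError(
                "DisplacementCurve.values length must match timestamps"
            )
        if self.normalized:
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise StreamValidationError(
                    "normalized DisplacementCurve.values must lie in [0, 1]"
                )
        elif self.values.min() < 0:
            raise StreamValidationError("raw DisplacementCurve.values must be >= 0")


@dataclass
class EventSeries:
    """Detected tap-cycle peaks or syllable onsets."""

    event_times: np.ndarray      # seconds, strictly increasing
    event_strengths: np.ndarray  # normalized intensity in [0, 1]
    recording_duration: float

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_strengths = np.asarray(self.event_strengths, dtype=float)
        if self.event_times.shape != self.event_strengths.shape:
            raise StreamValidationError("event_times / event_strengths length mismatch")
        if len(self.event_times) >= 2 and not np.all(np.diff(self.event_times) > 0):
            raise StreamValidationError("event_times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def intervals(self) -> np.ndarray:
        """Successive inter-event intervals (cycle durations), seconds."""
        return np.diff(self.event_times)


@dataclass
class FeatureSet:
    """The four movement/speech features for one recording.

    ``defined`` is False when fewer than 3 events were detected, in which
    case the feature values are NaN -- never fabricated zeros.
    """

    mean_frequency: float        # M-TF or M-SF, Hz
    cov_frequency: float         # COV-TF or COV-SF, dimensionless
    iiv: float                   # variance of cycle/syllable durations, s^2
    decrement_on_speed: float    # DoS, Hz/s, negative = slowing
    n_events: int
    source: str                  # {"video", "sensor", "audio", "latent"}
    test_label: str = ""
    defined: bool = True

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise StreamValidationError("n_events must be >= 0")
        if self.defined:
            if self.mean_frequency < 0 or self.cov_frequency < 0 or self.iiv < 0:
                raise StreamValidationError(
                    "mean_frequency, cov_frequency and iiv must be >= 0"
                )

    FEATURE_NAMES = ("mean_frequency", "cov_frequency", "iiv", "decrement_on_speed")

    def as_dict(self) -> dict:
        return {
            "mean_frequency": self.mean_frequency,
            "cov_frequency": self.cov_frequency,
            "iiv": self.iiv,
            "decrement_on_speed": self.decrement_on_speed,
            "n_events": self.n_events,
            "source": self.source,
            "test_label": self.test_label,
            "defined": self.defined,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def displacement_from_landmarks(stream: LandmarkStream) -> DisplacementCurve:
    """Per-frame 2D Euclidean distance between index fingertip and thumb tip."""
    d = np.linalg.norm(stream.index_xy - stream.thumb_xy, axis=1)
    return DisplacementCurve(stream.timestamps, d, normalized=False)


def displacement_from_sensors(stream: SensorStream) -> DisplacementCurve:
    """Per-sample 3D Euclidean distance between the two sensors."""
    d = np.linalg.norm(stream.sensor_a_xyz - stream.sensor_b_xyz, axis=1)
    return DisplacementCurve(stream.timestamps, d, normalized=False)


def normalize_curve(curve: DisplacementCurve) -> DisplacementCurve:
    """Min-max normalize a raw displacement curve to [0, 1].

    Raises
    ------
    DegenerateSignalError
        If the curve is constant (max == min): no tapping detected.
    """
    lo, hi = float(curve.values.min()), float(curve.values.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        raise DegenerateSignalError(
            "constant displacement curve (max == min): no tapping detected"
        )
    vals = (curve.values - lo) / (hi - lo)
    return DisplacementCurve(curve.timestamps, vals, normalized=True)


def segment_taps(
    curve: DisplacementCurve,
    min_prominence: float = 0.10,
    min_separation: float = 0.125,
    smoothing: bool = True,
) -> EventSeries:
    """Segment tap cycles as peaks (full aperture opening) of the curve.

    Peaks must have prominence >= ``min_prominence`` (normalized units) and
    pairwise time separation >= ``min_separation`` seconds.  A flat curve
    yields an empty series, not an exception.
    """
    if not curve.normalized:
        raise StreamValidationError("segment_taps expects a normalized curve")
    if not 0 < min_prominence < 1:
        raise StreamValidationError("min_prominence must be in (0, 1)")
    if min_separation <= 0:
        raise StreamValidationError("min_separation must be > 0")

    t = curve.timestamps
    v = curve.values
    if smoothing and len(v) >= 3:
        # 3-point moving average; endpoints kept as-is
        sm = v.copy()
        sm[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
        v = sm

    duration = float(t[-1] - t[0])
    peaks, props = sp_signal.find_peaks(v, prominence=min_prominence)
    if len(peaks) == 0:
        return EventSeries(np.array([]), np.array([]), duration)

    # enforce min time separation exactly (robust to dropped frames):
    # greedy keep-strongest in prominence order
    order = np.argsort(props["prominences"])[::-1]
    kept: list[int] = []
    for idx in order:
        p = peaks[idx]
        if all(abs(t[p] - t[q]) >= min_separation for q in kept):
            kept.append(p)
    kept.sort()
    kept_arr = np.array(kept, dtype=int)
    strengths = np.clip(curve.values[kept_arr], 0.0, 1.0)

    # sub-frame peak localization: 3-point parabola through each peak
    # (frame quantization alone is ~1/30 s, a visible rhythm artifact)
    times = t[kept_arr].copy()
    for j, p in enumerate(kept_arr):
        x = t[p - 1:p + 2]
        y = v[p - 1:p + 2]
        coef = np.polyfit(x - x[1], y, 2)
        if coef[0] < 0:
            vertex = x[1] - coef[1] / (2 * coef[0])
            times[j] = min(max(vertex, x[0]), x[2])
    return EventSeries(times, strengths, duration)


def features_from_events(
    events: EventSeries,
    source: str = "video",
    test_label: str = "",
    dos_method: str = "ols",
) -> FeatureSet:
    """Compute M-TF/M-SF, COV, IIV and DoS from an event series.

    With event times t_1..t_n, cycle durations d_k = t_{k+1} - t_k and
    instantaneous frequencies f_k = 1/d_k:

    * mean frequency = (n - 1) / (t_n - t_1), cycles per second over the
      first-event-to-last-event span (avoids edge truncation bias);
    * COV = SD(f) / mean(f) (sample SD, ddof=1);
    * IIV = unbiased variance of d, s^2;
    * DoS = OLS slope of f_k on cycle midpoint times, Hz/s; or, with
      ``dos_method="half_difference"``, the mean-frequency difference
      between the second and first half of the cycles divided by the time
      between the half midpoints.

    Fewer than 3 events make every feature undefined (NaN, ``defined=False``).
    """
    n = events.n_events
    if n < 3:
        logger.warning(
            "features undefined: %d event(s) detected, need >= 3", n
        )
        nan = float("nan")
        return FeatureSet(nan, nan, nan, nan, n, source, test_label, defined=False)

    t = events.event_times
    d = events.intervals
    f = 1.0 / d
    span = float(t[-1] - t[0])
    mean_frequency = (n - 1) / span
    cov = float(np.std(f, ddof=1) / np.mean(f))
    iiv = float(np.var(d, ddof=1))
    mid = (t[:-1] + t[1:]) / 2.0

    if dos_method == "ols":
        slope = float(np.polyfit(mid, f, 1)[0])
    elif dos_method == "half_difference":
        half = len(f) // 2
        f1, f2 = f[:half], f[half:]
        m1, m2 = float(np.mean(mid[:half])), float(np.mean(mid[half:]))
        if m2 == m1:
            slope = 0.0
        else:
            slope = float((np.mean(f2) - np.mean(f1)) / (m2 - m1))
    else:
        raise StreamValidationError(f"unknown dos_method: {dos_method!r}")

    return FeatureSet(mean_frequency, cov, iiv, slope, n, source, test_label)


def analyze_tapping(
    stream: LandmarkStream | SensorStream,
    config: RunConfig | None = None,
) -> FeatureSet:
    """Full tapping pipeline: displacement -> normalize -> segment -> features."""
    config = config or RunConfig()
    if isinstance(stream, LandmarkStream):
        source = "video"
        curve = _stage("displacement", displacement_from_landmarks, stream)
    elif isinstance(stream, SensorStream):
        source = "sensor"
        curve = _stage("displacement", displacement_from_sensors, stream)
    else:
        raise StreamValidationError(
            f"analyze_tapping expects a LandmarkStream or SensorStream, got {type(stream).__name__}"
        )
    norm = _stage("normalize", normalize_curve, curve)
    events = _stage(
        "segment",
        segment_taps,
        norm,
        min_prominence=config.min_prominence,
        min_separation=config.min_separation_s,
        smoothing=config.smoothing,
    )
    feats = _stage(
        "features",
        features_from_events,
        events,
        source=source,
        test_label=stream.test_label,
        dos_method=config.dos_method,
    )
    return feats


def _stage(name, fn, *args, **kw):
    """Run one pipeline stage, attaching the stage name to domain errors."""
    from .errors import TapDDKError

    try:
        return fn(*args, **kw)
    except TapDDKError as exc:
        if f"[{name}" in str(exc):
            raise
        raise type(exc)(f"[stage {name}] {exc}") from exc
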