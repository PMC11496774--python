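"""File readers and writers.

CSV dialects (UTF-8, comma separator, decimal point):

* landmark CSV — header ``frame,time_s,index_x,index_y,thumb_x,thumb_y``
  (``time_s`` optional; missing times are reconstructed as frame/fps,
  0-based);
* sensor CSV — header ``time_s,ax,ay,az,bx,by,bz`` at a nominal 60 Hz;
* feature CSV — one row per recording with every FeatureSet field plus the
  configuration hash (provenance);
* long-format feature CSV for validation — header
  ``recording_id,device_label,test_label,feature,source,value``; the row
  with ``device_label == "gold"`` in each (recording, test, feature) cell is
  the gold standard, any other label is the smartphone side.

WAV files are PCM 16-bit or float, mono or stereo (stereo is averaged to
mono with a logged warning); times serialize with 6 decimal places.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .agreement import PairedFeatureTable
from .errors import FormatError
from .kinematics import FeatureSet, LandmarkStream, SensorStream
from .speech import AudioWaveform

logger = logging.getLogger(__name__)

LANDMARK_COLUMNS = ["frame", "time_s", "index_x", "index_y", "thumb_x", "thumb_y"]
SENSOR_COLUMNS = ["time_s", "ax", "ay", "az", "bx", "by", "bz"]
LONG_COLUMNS = ["recording_id", "device_label", "test_label",
                "feature", "source", "value"]


def _read_csv(path: str | Path, required: list[str], optional: set[str] = frozenset()):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in df.columns:
        if col in required or col in optional:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                # +2: header line plus 1-based numbering
                raise FormatError(
                    f"{path}, line {bad[0] + 2}: unparseable value "
                    f"{df[col][bad[0]]!r} in column {col!r}"
                )
            df[col] = vals
    return df


def _check_monotone(times: np.ndarray, path) -> None:
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if len(bad):
        raise FormatError(
            f"{path}, line {bad[0] + 3}: non-monotone time_s "
            f"({times[bad[0] + 1]:.6f} after {times[bad[0]]:.6f})"
        )


def read_landmark_csv(path: str | Path, fps: float = 30.0,
                      test_label: str = "big_fast",
                      device_label: str = "") -> LandmarkStream:
    """Read a landmark CSV; frame/fps fills in missing ``time_s``."""
    df = _read_csv(path, LANDMARK_COLUMNS, optional={"time_s"})
    if "time_s" in df.columns and df["time_s"].notna().all():
        t = df["time_s"].to_numpy(float)
    else:
        t = df["frame"].to_numpy(float) / fps
    _check_monotone(t, path)
    return LandmarkStream(
        t, df[["index_x", "index_y"]].to_numpy(float),
        df[["thumb_x", "thumb_y"]].to_numpy(float),
        fps=fps, test_label=test_label, device_label=device_label,
    )


def write_landmark_csv(path: str | Path, stream: LandmarkStream) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(stream.timestamps)),
        "time_s": stream.timestamps,
        "index_x": stream.index_xy[:, 0], "index_y": stream.index_xy[:, 1],
        "thumb_x": stream.thumb_xy[:, 0], "thumb_y": stream.thumb_xy[:, 1],
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_sensor_csv(path: str | Path, sample_rate: float = 60.0,
                    test_label: str = "big_fast",
                    device_label: str = "gold") -> SensorStream:
    df = _read_csv(path, SENSOR_COLUMNS)
    t = df["time_s"].to_numpy(float)
    _check_monotone(t, path)
    return SensorStream(
        t, df[["ax", "ay", "az"]].to_numpy(float),
        df[["bx", "by", "bz"]].to_numpy(float),
        sample_rate=sample_rate, test_label=test_label,
        device_label=device_label,
    )


def write_sensor_csv(path: str | Path, stream: SensorStream) -> None:
    df = pd.DataFrame({
        "time_s": stream.timestamps,
        "ax": stream.sensor_a_xyz[:, 0], "ay": stream.sensor_a_xyz[:, 1],
        "az": stream.sensor_a_xyz[:, 2],
        "bx": stream.sensor_b_xyz[:, 0], "by": stream.sensor_b_xyz[:, 1],
        "bz": stream.sensor_b_xyz[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_wav(path: str | Path, test_label: str = "papapa",
             device_label: str = "") -> AudioWaveform:
    """Read a WAV file (PCM16/PCM32/float); stereo is averaged to mono."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read WAV ({exc})") from exc
    if not 8000 <= sr <= 96000:
        raise FormatError(f"{path}: sample rate {sr} Hz outside 8-96 kHz")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        logger.warning("%s: stereo input averaged to mono", path)
        data = data.mean(axis=1)
    return AudioWaveform(data, float(sr), test_label=test_label,
                         device_label=device_label)


def write_wav(path: str | Path, audio: AudioWaveform) -> None:
    pcm = np.clip(audio.samples, -1, 1)
    wavfile.write(path, int(audio.sample_rate),
                  (pcm * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_csv(path: str | Path, feature_sets: list[FeatureSet],
                      config_hash: str = "",
                      recording_ids: list[str] | None = None,
                      device_labels: list[str] | None = None) -> None:
    """One row per recording: all FeatureSet fields plus the config hash."""
    rows = []
    for i, fs in enumerate(feature_sets):
        row = {"recording_id": recording_ids[i] if recording_ids else f"rec{i:04d}",
               "device_label": device_labels[i] if device_labels else "",
               **fs.as_dict(), "config_hash": config_hash}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_long_feature_csv(path: str | Path, records: list[dict]) -> None:
    """Long-format table: one row per (recording, device, feature)."""
    rows = []
    for rec in records:
        for feat in FeatureSet.FEATURE_NAMES:
            rows.append({
                "recording_id": rec["recording_id"],
                "device_label": rec["device_label"],
                "test_label": rec["test_label"],
                "feature": feat,
                "source": rec.get("source", ""),
                "value": rec[feat],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_long_feature_csv(path: str | Path) -> list[PairedFeatureTable]:
    """Assemble PairedFeatureTables from a long-format feature CSV.

    Within each (recording, test, feature) cell the ``device_label ==
    "gold"`` row is the gold standard; exactly one other row (any label)
    is the smartphone measurement.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    tables = []
    for (feat, test), grp in df.groupby(["feature", "test_label"], sort=True):
        pairs, labels = [], []
        for rid, cell in grp.groupby("recording_id", sort=True):
            gold = cell[cell["device_label"] == "gold"]
            phone = cell[cell["device_label"] != "gold"]
            if len(gold) != 1 or len(phone) != 1:
                raise FormatError(
                    f"{path}: recording {rid!r}, feature {feat!r}, test "
                    f"{test!r}: need exactly one gold and one smartphone row, "
                    f"got {len(gold)} gold / {len(phone)} other"
                )
            pairs.append([float(phone["value"].iloc[0]),
                          float(gold["value"].iloc[0])])
            labels.append(str(phone["device_label"].iloc[0]))
        tables.append(PairedFeatureTable(feat, test, np.array(pairs), labels))
    return tables
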