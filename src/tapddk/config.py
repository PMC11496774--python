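"""Run configuration: every tunable of the analysis pipelines in one place.

The defaults are the documented package defaults; unknown keys are rejected
so that a typo in a YAML file fails loudly instead of silently falling back.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import TapDDKError


@dataclass
class RunConfig:
    # -- tap-cycle segmentation ------------------------------------------
    #: minimum peak prominence on the min-max normalized aperture curve
    min_prominence: float = 0.10
    #: minimum time between tap peaks, seconds (0.125 s caps detection at 8 Hz)
    min_separation_s: float = 0.125
    #: 3-point moving average before peak picking (suppresses landmark jitter)
    smoothing: bool = True

    # -- feature computation ---------------------------------------------
    #: "ols" = least-squares slope of instantaneous frequency vs time;
    #: "half_difference" = (mean f, 2nd half - 1st half) / half-span
    dos_method: str = "ols"

    # -- speech: denoising -----------------------------------------------
    #: fraction of lowest-energy frames used to estimate the noise profile
    noise_quantile: float = 0.1
    #: gate threshold = noise mean + gate_sd * noise SD, per frequency bin
    gate_sd: float = 1.5
    #: apply spectral gating before onset detection
    denoise: bool = True

    # -- speech: onset detection -----------------------------------------
    #: internal analysis sample rate, Hz
    audio_sr: int = 22050
    #: onset-envelope hop, seconds
    onset_hop_s: float = 0.010
    #: number of mel bands for the onset envelope
    n_mels: int = 40
    #: minimum time between syllable onsets, seconds (caps at 10 syll/s)
    onset_min_separation_s: float = 0.1
    #: event threshold = rel_threshold * (1 s moving mean + floor)
    onset_rel_threshold: float = 1.5
    #: additive global floor on the normalized strength curve
    onset_floor: float = 0.05

    # -- agreement statistics --------------------------------------------
    #: "paired" (classical paired t) or "welch" (two-sample, unequal variance)
    t_test_mode: str = "paired"
    #: limits-of-agreement multiplier on SD of differences
    loa_multiplier: float = 1.96
    #: agreement tolerance, feature units (Hz for frequencies)
    tolerance: float = 1.0

    # -- run plumbing ----------------------------------------------------
    seed: int = 0
    out_dir: str = "tapddk_out"

    def __post_init__(self) -> None:
        if not 0 < self.min_prominence < 1:
            raise TapDDKError("min_prominence must be in (0, 1)")
        if self.min_separation_s <= 0:
            raise TapDDKError("min_separation_s must be > 0")
        if not 0 < self.noise_quantile < 1:
            raise TapDDKError("noise_quantile must be in (0, 1)")
        if self.gate_sd < 0:
            raise TapDDKError("gate_sd must be >= 0")
        if self.dos_method not in ("ols", "half_difference"):
            raise TapDDKError(f"unknown dos_method: {self.dos_method!r}")
        if self.t_test_mode not in ("paired", "welch"):
            raise TapDDKError(f"unknown t_test_mode: {self.t_test_mode!r}")
        if self.tolerance <= 0:
            raise TapDDKError("tolerance must be > 0")

    # -- (de)serialization ------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise TapDDKError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise TapDDKError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def hash(self) -> str:
        """Short stable digest of the full configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
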