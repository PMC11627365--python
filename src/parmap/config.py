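"""Pipeline configuration (YAML) and the run manifest."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .errors import ConfigError

_ALLOWED_KEYS = None  # populated below from the dataclass fields


@dataclass
class PipelineConfig:
    """All parameters of an end-to-end run, serialized into every output
    directory so any run can be reproduced from its manifest."""

    images_dir: str = ""
    controls_dir: str = ""
    output_dir: str = "parmap_out"
    tracks_csv: str | None = None
    events_csv: str | None = None
    # channel roles
    signal_channel: str = "apar"
    ppar_channel: str | None = "ppar"
    af_channel: str = "af"
    anterior_marker: str | None = "apar"
    # correction
    correction_mode: str = "pixel"  # pixel | embryo
    local_bg_tiff: str | None = None
    # cortex quantitation
    width_px: int = 50
    smooth_window_px: int = 20
    fraction: float = 0.33
    n_contour_points: int = 1000
    # dosage controls: image filenames (within images_dir) that are
    # control-RNAi embryos; they define dosage = 1 and wild-type peaks
    dosage_controls: list[str] = field(default_factory=list)
    # domain-call thresholds (proxy classifier free parameters)
    theta_high: float = 1.5
    theta_low: float = 1.2
    min_arc: float = 0.05
    # dose-response
    trend_phenotypes: list[str] = field(default_factory=list)
    span: float = 0.3
    half_width: float = 0.1
    half_width_is_fwhm: bool = False
    n_boot: int = 1000
    seed: int = 0
    version: str = "parmap-0.1.0"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if self.correction_mode not in ("pixel", "embryo"):
            raise ConfigError("correction_mode must be 'pixel' or 'embryo'")
        if not 0 < self.fraction <= 1:
            raise ConfigError("fraction must lie in (0, 1]")
        if self.width_px < 20:
            raise ConfigError("width_px must be >= 20")
        if self.n_boot < 1 or self.span <= 0 or self.half_width <= 0:
            raise ConfigError("n_boot, span and half_width must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written atomically at the end of a run."""

    config_hash: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        os.replace(tmp, path)


def checksum_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
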