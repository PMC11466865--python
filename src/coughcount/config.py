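"""Run configuration: every tunable of the pipeline in one nested record.

Loaded from YAML (unknown keys are rejected, so typos fail loudly) and
hashable, so every result can record exactly which configuration produced
it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .audio_io import DEFAULT_SAMPLE_RATE
from .cepstral import CepstralConfig
from .denoise import WaveletDenoiseParams
from .endpoint import EndpointConfig
from .shorttime import FrameGrid


@dataclass(frozen=True)
class FrameConfig:
    """Framing parameters in milliseconds (resolved against the sample rate)."""

    length_ms: float = 25.0
    hop_ms: float = 10.0
    window: str = "rectangular"

    def grid(self, sample_rate: int) -> FrameGrid:
        return FrameGrid.from_ms(sample_rate, self.length_ms, self.hop_ms, self.window)  # type: ignore[arg-type]


@dataclass(frozen=True)
class FilterbankConfig:
    """Mel filterbank extent; fft_size bins at the pipeline sample rate."""

    n_filters: int = 26
    fft_size: int = 512
    f_low: float = 30.0
    f_high: float = 4000.0


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass(frozen=True)
class RunConfig:
    """The full pipeline configuration."""

    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0
    log_level: str = "INFO"
    denoise_enabled: bool = True
    denoise: WaveletDenoiseParams = field(default_factory=WaveletDenoiseParams)
    frames: FrameConfig = field(default_factory=FrameConfig)
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)
    cepstral: CepstralConfig = field(default_factory=CepstralConfig)
    filterbank: FilterbankConfig = field(default_factory=FilterbankConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_updates(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)


_SECTION_TYPES = {
    "denoise": WaveletDenoiseParams,
    "frames": FrameConfig,
    "endpoint": EndpointConfig,
    "cepstral": CepstralConfig,
    "filterbank": FilterbankConfig,
    "classifier": ClassifierConfig,
}

# YAML keys allowed per section (spec'd config surface maps onto dataclass
# field names; e.g. denoise.wavelet -> wavelet_name)
_KEY_ALIASES = {
    ("denoise", "wavelet"): "wavelet_name",
    ("denoise", "mode"): "threshold_mode",
    ("denoise", "rule"): "threshold_rule",
    ("denoise", "scale"): "per_level_scale",
}


def _build_section(name: str, raw: dict[str, Any]) -> Any:
    cls = _SECTION_TYPES[name]
    valid = {f.name for f in fields(cls)}
    resolved: dict[str, Any] = {}
    for key, value in raw.items():
        key = _KEY_ALIASES.get((name, key), key)
        if key not in valid:
            raise ValueError(f"unknown config key {name}.{key}")
        resolved[key] = value
    return cls(**resolved)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig`, rejecting unknown keys at any depth."""
    kwargs: dict[str, Any] = {}
    scalar = {"sample_rate", "seed", "log_level", "denoise_enabled"}
    for key, value in (raw or {}).items():
        if key in scalar:
            kwargs[key] = value
        elif key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build_section(key, value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file (None or missing content -> defaults)."""
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return config_from_dict(raw)
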