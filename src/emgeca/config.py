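"""Pipeline configuration: nested sections, strict YAML/JSON loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .errors import ValidationError
from .model import EcaConfig, ModelSpec, TrainConfig
from .preprocess import EnvelopeConfig
from .stream import StreamConfig
from .synth import AcquisitionProtocol
from .windows import WindowConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs; defaults mirror the study setup
    (300/100 ms windows, Adam 1e-4, 300 epochs, batch 128, 8 gestures at
    1000 Hz)."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    eca: EcaConfig = field(default_factory=EcaConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    stream: StreamConfig = field(default_factory=StreamConfig)
    seed: int = 0
    out_root: str = "runs"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.protocol.validate()
        self.envelope.validate(self.protocol.fs)
        self.window.validate()
        self.model.validate()
        self.eca.validate()
        self.train.validate()
        self.stream.validate()


_TUPLE_OF_TUPLES = {"conv_kernels", "conv_strides"}


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValidationError(f"{path or cls.__name__}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        here = f"{path}.{key}" if path else key
        if key not in known:
            raise ValidationError(f"unknown configuration key '{here}'")
        ftype = known[key].default_factory if known[key].default_factory is not dataclasses.MISSING else None
        default = ftype() if ftype else known[key].default
        if is_dataclass(default):
            kwargs[key] = _build_dataclass(type(default), value or {}, here)
        elif isinstance(value, list):
            if key in _TUPLE_OF_TUPLES:
                kwargs[key] = tuple(tuple(v) for v in value)
            else:
                kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"{path or cls.__name__}: {exc}") from exc


def config_from_dict(data: dict | None) -> PipelineConfig:
    cfg = _build_dataclass(PipelineConfig, data or {}, "")
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) pipeline config; omitted keys take
    the defaults, unknown keys are rejected with their location."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file {path} does not exist")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg: PipelineConfig) -> dict:
    return _to_plain(cfg)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
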