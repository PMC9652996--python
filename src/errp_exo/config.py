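"""Pipeline configuration: one hierarchical key-value (YAML) document.

Unknown keys are rejected; every default is the dataclass default, so an
empty document is a valid full-size run configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from errp_exo.preprocess import PreprocessConfig


@dataclass(frozen=True)
class GeneratorOptions:
    n_subjects: int = 5
    effect_scale: float = 1.0
    noise_rms_uv: float | None = None     # None: generator default
    blink_rate_per_min: float | None = None
    episodes_per_block: int | None = None  # None: protocol default (8)
    events_per_episode: tuple[int, int] | None = None


@dataclass(frozen=True)
class DecoderOptions:
    n_folds: int = 10
    n_repeats: int = 10
    variance_target: float = 0.95
    modalities: tuple[str, ...] = ("eeg", "emg", "kinematics")
    schemes: tuple[str, ...] = ("combined", "gravity", "myoprocessor")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    generator: GeneratorOptions = field(default_factory=GeneratorOptions)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decoder: DecoderOptions = field(default_factory=DecoderOptions)
    write_raw: bool = False       # also persist continuous streams (large)
    make_figures: bool = True     # grand-average ERP, Tukey mask, accuracy bars


def _from_dict(cls, doc: dict):
    if not isinstance(doc, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(doc).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, val in doc.items():
        sub = known[key].type
        if key in ("generator", "preprocess", "decoder"):
            target = {"generator": GeneratorOptions, "preprocess": PreprocessConfig,
                      "decoder": DecoderOptions}[key]
            kwargs[key] = _from_dict(target, val)
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    doc = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        doc = _merge(doc, overrides)
    return _from_dict(PipelineConfig, doc)


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def config_echo(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_echo(cfg), sort_keys=False))
    return path
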