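"""Pipeline configuration: nested key-value tree -> validated dataclasses.

Defaults: learning rate 0.001, 50 epochs, batch size 32, Adam, L2 0.01,
dropout 0.5, polynomial kernel of degree 3 with scale 1.0 and offset 0.0,
80/20 stratified split. Unknown keys
are rejected by name; all violations are reported together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .cae import AEConfig
from .enhance import EnhanceConfig
from .exceptions import ConfigError
from .gan import GanConfig
from .qsvm import KernelSpec


@dataclass
class DatasetConfig:
    root: str | None = None  # class-folder dataset; None -> synthetic fixtures
    image_size: int = 64
    n_classes: int = 7
    counts_per_class: tuple[int, ...] | None = None  # fixtures only; default 70 each
    background_noise_sd: float = 0.02
    permute_labels: bool = False  # diagnostic: destroys the image-label link


@dataclass
class PipelineConfig:
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    enhance_enabled: bool = True
    gan: GanConfig = field(default_factory=GanConfig)
    gan_enabled: bool = False
    cae: AEConfig = field(default_factory=AEConfig)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    svm_c: float = 1.0
    split_fraction: float = 0.8
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        self.enhance.validate()
        self.kernel.validate()
        self.cae.validate()
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError(
                f"split_fraction must be in (0,1), got {self.split_fraction}"
            )
        if self.svm_c <= 0:
            raise ConfigError(f"svm_c must be > 0, got {self.svm_c}")


_SECTIONS = {
    "dataset": DatasetConfig,
    "enhance": EnhanceConfig,
    "gan": GanConfig,
    "cae": AEConfig,
    "kernel": KernelSpec,
}


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def _build_section(dc_cls, raw: dict, path: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(dc_cls)}
    unknown = set(raw) - known
    for k in sorted(unknown):
        errors.append(f"unknown key '{path}.{k}'")
    kwargs = {k: _tuplify(v) for k, v in raw.items() if k in known}
    try:
        return dc_cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"invalid section '{path}': {exc}")
        return dc_cls()


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a PipelineConfig from a nested key-value tree."""
    raw = dict(raw or {})
    errors: list[str] = []
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_fields
    for k in sorted(unknown):
        errors.append(f"unknown key '{k}'")

    kwargs = {}
    for name, dc_cls in _SECTIONS.items():
        section = raw.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            errors.append(f"section '{name}' must be a mapping")
            section = {}
        kwargs[name] = _build_section(dc_cls, section, name, errors)
    for name in top_fields - set(_SECTIONS):
        if name in raw:
            kwargs[name] = _tuplify(raw[name])

    cfg = None
    if not errors:
        try:
            cfg = PipelineConfig(**kwargs)
            cfg.validate()
        except (ConfigError, TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Inverse of validate_config up to list/tuple spelling."""
    return dataclasses.asdict(cfg)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def save_config(cfg: PipelineConfig, path) -> None:
    def listify(v):
        if isinstance(v, tuple):
            return [listify(x) for x in v]
        if isinstance(v, dict):
            return {k: listify(x) for k, x in v.items()}
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(listify(config_to_dict(cfg)), fh, sort_keys=False)
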