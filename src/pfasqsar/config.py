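"""Pipeline configuration: strict parsing, defaults, and provenance.

Configs are YAML or JSON.  Unknown keys are fatal (typo guard) and the seed
is mandatory.  Every resolved value records whether it came from the user or
from a default, and the resolved config serializes back to a re-parseable
document.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = [
    "InputConfig",
    "FeaturizeConfig",
    "MetricConfig",
    "EmbedConfig",
    "ClusterConfig",
    "MotifConfig",
    "AffinityConfig",
    "PipelineConfig",
    "validate_config",
    "config_from_dict",
]


@dataclass
class InputConfig:
    molecules: str = ""
    affinities: str | None = None


@dataclass
class FeaturizeConfig:
    n_bits: int = 2048
    use_affinity: bool = False
    affinity_scale: float | None = None  # None -> auto (bit-comparable std)


@dataclass
class MetricConfig:
    d_out: int = 64
    margin: float = 1.0
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 256
    max_pairs: int = 2000


@dataclass
class EmbedConfig:
    pca_components: int = 50
    tsne: bool = False
    perplexity: float = 30.0


@dataclass
class ClusterConfig:
    k: int | None = None  # fixed k; mutually exclusive with k_grid
    k_grid: list[int] | None = None
    n_init: int = 10
    space: str = "pca"  # or "tsne"


@dataclass
class MotifConfig:
    completion_threshold: float = 0.8
    top_clusters: int = 5
    min_support: int = 10  # labeled matches a headline motif must reach
    ester_smarts: str = "[CX3](=O)[OX2][#6]"
    mcs_timeout: int = 10


@dataclass
class AffinityConfig:
    threshold: float = -5.0


@dataclass
class PipelineConfig:
    input: InputConfig = field(default_factory=InputConfig)
    target: str = "T1"
    filter: str = "none"  # none | cf | c3f6
    featurize: FeaturizeConfig = field(default_factory=FeaturizeConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    affinity: AffinityConfig = field(default_factory=AffinityConfig)
    seed: int | None = None
    output_dir: str = "run"
    provenance: dict[str, str] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        data = asdict(self)
        data.pop("provenance", None)
        return data

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not self.input.molecules:
            raise ConfigError("input.molecules is mandatory")
        if not Path(self.input.molecules).exists():
            raise ConfigError(f"input.molecules does not exist: {self.input.molecules}")
        if self.input.affinities is not None and not Path(self.input.affinities).exists():
            raise ConfigError(
                f"input.affinities does not exist: {self.input.affinities}"
            )
        if self.filter not in ("none", "cf", "c3f6"):
            raise ConfigError(f"filter must be none|cf|c3f6, got {self.filter!r}")
        if self.cluster.space not in ("pca", "tsne"):
            raise ConfigError(f"cluster.space must be pca|tsne, got {self.cluster.space!r}")
        if self.cluster.space == "tsne" and not self.embed.tsne:
            raise ConfigError("cluster.space=tsne requires embed.tsne=true")
        if self.cluster.k is not None and self.cluster.k_grid is not None:
            raise ConfigError("cluster.k and cluster.k_grid are mutually exclusive")
        if self.featurize.use_affinity and self.input.affinities is None:
            raise ConfigError("featurize.use_affinity requires input.affinities")


def _fill(cls, data: dict, prefix: str, provenance: dict[str, str]):
    if not isinstance(data, dict):
        raise ConfigError(f"section {prefix or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(cls) if f.name != "provenance"}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} in section {prefix or '<root>'}"
        )
    kwargs = {}
    for name, f in known.items():
        dotted = f"{prefix}{name}"
        sub_type = f.type if isinstance(f.type, type) else None
        default_obj = None
        if is_dataclass_field(f):
            default_obj = f.default_factory()  # type: ignore[misc]
        if name in data:
            if default_obj is not None and is_dataclass(default_obj):
                kwargs[name] = _fill(
                    type(default_obj), data[name], dotted + ".", provenance
                )
            else:
                kwargs[name] = data[name]
                provenance[dotted] = "user"
        else:
            if default_obj is not None and is_dataclass(default_obj):
                kwargs[name] = _fill(type(default_obj), {}, dotted + ".", provenance)
            else:
                provenance[dotted] = "default"
    return cls(**kwargs)


def is_dataclass_field(f) -> bool:
    try:
        return f.default_factory is not None and is_dataclass(f.default_factory())  # type: ignore[misc]
    except TypeError:
        return False


def config_from_dict(data: dict) -> PipelineConfig:
    provenance: dict[str, str] = {}
    cfg = _fill(PipelineConfig, data, "", provenance)
    cfg.provenance = provenance
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default-fill, and validate a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"config does not parse: {exc}") from exc
    if data is None:
        data = {}
    cfg = config_from_dict(data)
    cfg.validate()
    return cfg
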