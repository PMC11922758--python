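"""Pipeline configuration: nested dataclass sections with strict YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._validate import ValidationError
from .effectors import EffectorConfig
from .crossspecies import MatchConfig
from .qc import QCConfig
from .spatial import SignatureGeneFilterConfig
from .tree import PruneConfig


@dataclass(frozen=True)
class SimulateConfig:
    """Sizes for the synthetic demo dataset driven by ``run-all``."""

    levels: tuple = (2, 3)
    cells_per_leaf: int = 120
    embedding_dim: int = 10
    separation: float = 8.0
    noise_sd: float = 1.0
    n_genes: int = 300
    markers_per_leaf: int = 5
    shared_leaves: int = 8
    private_leaves: int = 2
    n_regions: int = 5
    spots_per_region: int = 40
    n_planted_spatial: int = 8
    n_flat_spatial: int = 4
    spatial_noise_sd: float = 0.5
    n_gwas_genes: int = 2000
    n_celltypes: int = 10
    n_planted_effectors: int = 40


@dataclass(frozen=True)
class ClusteringConfig:
    """One consensus layer per resolution; ``k_neighbors`` aligns with
    ``resolutions`` (coarse layers need neighbourhoods larger than one
    cluster for the graph to expose coarse structure)."""

    resolutions: tuple = (0.05, 0.5)
    k_neighbors: tuple = (160, 15)
    n_runs: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "hypoatlas_output"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    signature: SignatureGeneFilterConfig = field(default_factory=SignatureGeneFilterConfig)
    effectors: EffectorConfig = field(default_factory=EffectorConfig)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def _plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [_plain(v) for v in obj]
            return obj

        return _plain(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        return _build(cls, payload, "config")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _build(klass, payload: dict, where: str):
    names = {f.name: f for f in dataclasses.fields(klass)}
    unknown = set(payload) - set(names)
    if unknown:
        raise ValidationError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            sub = f.default_factory if f.default_factory is not dataclasses.MISSING else f.type
            if not isinstance(value, dict):
                raise ValidationError(f"{where}.{key}: expected a mapping")
            kwargs[key] = _build(sub, value, f"{where}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return klass(**kwargs)
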