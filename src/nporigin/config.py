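"""Layered pipeline configuration.

Defaults match the published analysis settings (1024 fingerprint
dimensions, radii {1, 2}, 32 LSH trees, 20 nearest neighbors, 5 folds,
C grid {0.01, 0.1, 1, 10, 100}). Values are resolved in layers:
built-in defaults < config file (JSON or YAML) < environment variables
(``NPORIGIN_*``, handled by the CLI) < command-line flags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .classifier import DEFAULT_C_GRID
from .errors import ConfigurationError
from .fingerprints import DEFAULT_DIMENSIONS, DEFAULT_HASH_SEED, DEFAULT_RADII
from .layout import DEFAULT_K_NEIGHBORS, DEFAULT_N_TREES
from .synthetic import SynthConfig


@dataclass(frozen=True)
class FingerprintConfig:
    d: int = DEFAULT_DIMENSIONS
    radii: tuple[int, ...] = DEFAULT_RADII
    seed: int = DEFAULT_HASH_SEED


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "map4_match"
    gamma: float | None = None
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class LayoutConfig:
    n_trees: int = DEFAULT_N_TREES
    k: int = DEFAULT_K_NEIGHBORS
    seed: int = 0


@dataclass(frozen=True)
class CurationConfig:
    id_column: str = "id"
    smiles_column: str = "smiles"
    taxonomy_column: str = "taxonomy"
    doi_column: str = "doi"

    def column_map(self) -> dict[str, str]:
        return {"id": self.id_column, "smiles": self.smiles_column,
                "taxonomy": self.taxonomy_column, "doi": self.doi_column}


@dataclass(frozen=True)
class PipelineConfig:
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    synthetic: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, section):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - fields
            if unknown:
                raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
            section = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return klass(**section)

        return cls(
            fingerprint=build(FingerprintConfig, data.get("fingerprint", {})),
            classifier=build(ClassifierConfig, data.get("classifier", {})),
            layout=build(LayoutConfig, data.get("layout", {})),
            curation=build(CurationConfig, data.get("curation", {})),
            synthetic=build(SynthConfig, data.get("synthetic", {})),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def write_manifest(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
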