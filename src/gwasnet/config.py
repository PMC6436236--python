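"""Pipeline configuration (YAML) and deterministic per-stage seeding."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .apcst import ApcstConfig
from .variant_link import RegressionConfig


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: mixes the global seed with a stage-name hash
    so each stage is individually reproducible."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class LocusInputs:
    locus_id: str
    gwas: str
    exons_bed: str
    distal_bed: str
    tss: str
    eqtl: str


@dataclass
class TraitInputs:
    trait: str
    genewise: str


@dataclass
class TissueInputs:
    tissue: str
    expression: str


@dataclass
class SemanticOptions:
    share: float = 0.5
    space: str = "reduced"
    stopwords: str | None = None


@dataclass
class EnrichmentOptions:
    n_perm: int = 1000
    window_bp: int = 1_000_000


@dataclass
class TissueFilterOptions:
    tpm_threshold: float = 0.1
    sample_fraction: float = 0.5


@dataclass
class PipelineConfig:
    loci: list[LocusInputs]
    corpus: str
    query: str
    interactome: str
    traits: list[TraitInputs] = field(default_factory=list)
    lead_snps: str | None = None
    tissues: list[TissueInputs] = field(default_factory=list)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    semantic: SemanticOptions = field(default_factory=SemanticOptions)
    candidacy_threshold: float = 0.70
    exon_scale: float = 10.0
    apcst: ApcstConfig = field(default_factory=ApcstConfig)
    n_random_specificity: int = 100
    enrichment: EnrichmentOptions = field(default_factory=EnrichmentOptions)
    tissue_filter: TissueFilterOptions = field(default_factory=TissueFilterOptions)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


_NESTED = {
    "loci": LocusInputs,
    "traits": TraitInputs,
    "tissues": TissueInputs,
    "regression": RegressionConfig,
    "semantic": SemanticOptions,
    "apcst": ApcstConfig,
    "enrichment": EnrichmentOptions,
    "tissue_filter": TissueFilterOptions,
}


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML config (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    kwargs = {}
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        cls = _NESTED.get(key)
        if cls is None:
            kwargs[key] = value
        elif isinstance(value, list):
            kwargs[key] = [_build(cls, item) for item in value]
        else:
            kwargs[key] = _build(cls, value or {})
    return PipelineConfig(**kwargs)
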