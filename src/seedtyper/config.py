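"""Pipeline configuration: thresholds, defaults, and input paths.

The configuration round-trips losslessly through YAML; unknown keys are
rejected so typos fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InputError
from .genotyping import GenotypeThresholds
from .simulate import SimParams

_INPUT_KEYS = {
    "markers_vcf",
    "counts_tsv",
    "seeds_tsv",
    "hotspots_bed",
    "sections_bed",
    "mut_counts_tsv",
    "mut_seeds_tsv",
    "interval_bed",
}


@dataclass
class PipelineConfig:
    # genotype calling
    min_depth: int = 30
    max_fraction_nocall: float = 0.2
    hom_ref_min: float = 0.9
    hom_alt_max: float = 0.1
    het_low: float = 0.3
    het_high: float = 0.7
    # crossover calling
    min_flank: int = 2
    thin_spacing_bp: int = 100  # 100 bp suits dense ~26 kb intervals; 400 bp sparser ~50 kb ones
    # landscape
    bin_width_bp: int = 200
    snps_only_density: bool = False
    # genetic totals (cM); inferred from seed counts when not given
    total_cm: float | None = None
    mut_total_cm: float | None = None
    rng_seed: int = 0
    simulate: SimParams = field(default_factory=SimParams)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimParams.from_dict(self.simulate)
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise InputError(f"unknown input keys: {sorted(unknown)}")
        if self.min_flank < 1:
            raise InputError("min_flank must be >= 1")
        if self.thin_spacing_bp < 0:
            raise InputError("thin_spacing_bp must be >= 0")
        if self.bin_width_bp < 1:
            raise InputError("bin_width_bp must be >= 1")
        self.thresholds()  # validates the genotype bands

    def thresholds(self) -> GenotypeThresholds:
        return GenotypeThresholds(
            min_depth=self.min_depth,
            hom_ref_min=self.hom_ref_min,
            hom_alt_max=self.hom_alt_max,
            het_low=self.het_low,
            het_high=self.het_high,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
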