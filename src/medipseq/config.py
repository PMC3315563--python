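"""Pipeline configuration: every tunable constant in one round-trippable
structure (YAML on disk)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class GenomeConfig:
    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 50
    n_repeats_per_class: int = 40
    shore_mode: str = "flanks"  # or "tss_upstream"


@dataclass
class CohortConfig:
    seed: int = 2
    noise_sd: float = 0.05
    null: bool = False  # True -> no implanted DMRs


@dataclass
class FragmentConfig:
    seed: int = 3
    n_fragments: int = 30_000
    length_mean: float = 450.0
    length_sd: float = 100.0
    background_rate: float = 0.05
    duplicate_frac: float = 0.05
    lowq_frac: float = 0.05
    mapq_min: int = 10


@dataclass
class QuantConfig:
    seed: int = 4
    burn_in: int = 200
    draws: int = 800
    proposal_width: float = 0.1
    c_min: float = 0.5
    smooth_l1: float = 25.0
    smooth_l2: float = 0.0


@dataclass
class DmrConfig:
    p_thresh: float = 0.05
    delta_thresh: float = 0.25
    p_select: float = 0.001
    percentile: float = 0.99
    min_windows: int = 1


@dataclass
class ClusterConfig:
    seed: int = 5
    k_max: int = 4
    n_folds: int = 5


@dataclass
class ExpressionConfig:
    seed: int = 6
    coupling_strength: float = -4.0
    noise_sd: float = 0.5


@dataclass
class PipelineConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fragments: FragmentConfig = field(default_factory=FragmentConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    dmr: DmrConfig = field(default_factory=DmrConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        if not (0 < self.dmr.p_thresh <= 1 and 0 < self.dmr.p_select <= 1):
            raise ValueError("p thresholds must lie in (0, 1]")
        if not (0 <= self.dmr.delta_thresh <= 1):
            raise ValueError("delta threshold must lie in [0, 1]")
        if not (0 < self.dmr.percentile < 1):
            raise ValueError("percentile must lie in (0, 1)")
        if self.fragments.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if not (0 <= self.fragments.background_rate < 1):
            raise ValueError("background_rate must lie in [0, 1)")
        if self.quant.c_min <= 0:
            raise ValueError("c_min must be > 0")
        if self.cluster.k_max < 2 or self.cluster.n_folds < 2:
            raise ValueError("k_max and n_folds must be >= 2")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            genome=GenomeConfig(**raw.get("genome", {})),
            cohort=CohortConfig(**raw.get("cohort", {})),
            fragments=FragmentConfig(**raw.get("fragments", {})),
            quant=QuantConfig(**raw.get("quant", {})),
            dmr=DmrConfig(**raw.get("dmr", {})),
            cluster=ClusterConfig(**raw.get("cluster", {})),
            expression=ExpressionConfig(**raw.get("expression", {})),
        )
        cfg.validate()
        return cfg

    def apply_overrides(self, overrides: dict[str, str]) -> None:
        """Apply ``section.key=value`` overrides (CLI precedence)."""
        for dotted, value in overrides.items():
            section, _, key = dotted.partition(".")
            target = getattr(self, section, None)
            if target is None or not hasattr(target, key):
                raise KeyError(f"unknown config key {dotted!r}")
            current = getattr(target, key)
            cast = type(current)
            setattr(target, key, cast(value) if not isinstance(current, bool) else value in ("1", "true", "True"))
        self.validate()
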