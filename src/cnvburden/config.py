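"""Configuration dataclasses for simulation, filtering and the pipeline.

All stages are pure functions of (inputs, config, seed); configs are plain
dataclasses serialisable to/from YAML or JSON so a run can be reproduced
from the echoed config file alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Default cohort sizes: five community cohorts of older adults, sized like
#: the fluid-intelligence analysis sample (total N = 3,133).
DEFAULT_COHORT_SIZES: dict[str, int] = {
    "ABC1936": 346,
    "LBC1921": 482,
    "LBC1936": 877,
    "Manchester": 730,
    "Newcastle": 698,
}

#: Cohort age structure (mean, SD in years). The birth cohorts have very
#: narrow age ranges (everyone born the same year, tested together); the
#: volunteer cohorts are much wider.
DEFAULT_COHORT_AGES: dict[str, tuple[float, float]] = {
    "ABC1936": (64.6, 0.9),
    "LBC1921": (79.1, 0.6),
    "LBC1936": (69.5, 0.8),
    "Manchester": (65.6, 8.0),
    "Newcastle": (66.0, 8.0),
}

#: Cohorts whose fluid phenotype is derived separately for males and females.
DEFAULT_SEX_STRATIFIED_COHORTS: tuple[str, ...] = ("Manchester", "Newcastle")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the study conditions this pipeline targets: five
    cohorts of community-dwelling older adults, long rare CNVs at an
    expected rate of 0.053 per individual of which 24.6% are deletions,
    two noisy callers observing a common truth set, and cognitive test
    batteries driven by one shared latent factor.
    """

    n_samples_per_cohort: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    # rare-CNV genetic architecture
    cnv_rate: float = 0.053            # expected rare CNVs per individual
    deletion_fraction: float = 0.246   # share of rare CNVs that are deletions
    length_min_bp: int = 500_000       # log-uniform length range
    length_max_bp: int = 3_000_000
    n_common_loci: int = 0             # optional common CNV loci (>1% carriers)
    common_carrier_fraction: float = 0.05
    # caller noise model
    caller_boundary_jitter_bp: int = 10_000
    caller_miss_rate: float = 0.05
    split_probability: float = 0.05
    # phenotype model
    effect_beta_count: float = 0.0     # standardized effects of CNV burden
    effect_beta_length: float = 0.0
    effect_beta_genes: float = 0.0
    n_subtests: int = 4
    factor_loading: float = 0.7        # subtest loading on the latent factor
    # sample-level QC metric model
    bad_lrr_fraction: float = 0.02     # samples with LRR SD > 0.3
    noisy_cnv_fraction: float = 0.01   # samples with >= 30 CNVs > 100 kb
    n_duplicate_pairs: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "deletion_fraction",
            "caller_miss_rate",
            "split_probability",
            "bad_lrr_fraction",
            "noisy_cnv_fraction",
            "common_carrier_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cnv_rate < 0:
            raise ValueError("cnv_rate must be >= 0")
        if self.length_min_bp <= 0 or self.length_max_bp < self.length_min_bp:
            raise ValueError("invalid CNV length range")
        if not self.n_samples_per_cohort:
            raise ValueError("need at least one cohort")
        if any(n <= 0 for n in self.n_samples_per_cohort.values()):
            raise ValueError("cohort sizes must be positive")
        if self.caller_boundary_jitter_bp < 0:
            raise ValueError("caller_boundary_jitter_bp must be >= 0")


@dataclass
class FilterConfig:
    """Sample- and CNV-level quality-control thresholds.

    Samples with LRR SD above ``lrr_sd_max`` or with ``max_cnvs_gt_100kb``
    or more CNVs longer than 100 kb are excluded; consensus CNVs must span
    at least ``min_markers`` markers and ``min_length_bp`` base pairs, and
    no marker along a kept CNV may lie in a CNV in more than
    ``max_frequency`` of the sample's cohort.
    """

    lrr_sd_max: float = 0.3
    max_cnvs_gt_100kb: int = 30
    min_markers: int = 15
    min_length_bp: int = 500_000
    max_frequency: float = 0.01
    frequency_scope: str = "per_cohort"  # or "whole_sample"

    def validate(self) -> None:
        if self.lrr_sd_max <= 0 or self.min_markers <= 0 or self.min_length_bp <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.max_frequency < 1.0:
            raise ValueError("max_frequency must be in (0, 1)")
        if self.frequency_scope not in ("per_cohort", "whole_sample"):
            raise ValueError(f"unknown frequency_scope {self.frequency_scope!r}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: simulation, filters, association."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    # marker map
    n_chromosomes: int = 22
    markers_per_chromosome: int = 2000
    chromosome_length_bp: int = 50_000_000
    # burden
    pad_bp: int = 20_000
    # candidate-region panel
    n_regions: int = 20
    # association
    n_permutations: int = 1_000
    maxt_signed: bool = False
    within_cohort: bool = False
    merge_min_member_length_bp: int = 200_000
    merge_max_gap_fraction: float = 0.5
    sex_stratified_cohorts: tuple[str, ...] = DEFAULT_SEX_STRATIFIED_COHORTS
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        self.filters.validate()
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("marker map dimensions must be >= 1")


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small configuration (500 samples, B = 1,000) for quick runs.

    Two cohorts of 250 rather than five tiny ones: with a 1% rarity
    threshold a cohort must exceed 100 samples for a single carrier to
    count as rare, so very small cohorts would discard every CNV.
    """
    sim = SimulationConfig(
        n_samples_per_cohort={"cohort_1": 250, "cohort_2": 250},
        seed=seed,
    )
    cfg = PipelineConfig(simulation=sim, n_permutations=1_000, seed=seed)
    cfg.n_chromosomes = 8
    cfg.markers_per_chromosome = 1500
    return cfg


def _asdict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Serialise a pipeline config to YAML or JSON (by extension)."""
    path = Path(path)
    d = _asdict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON (auto-detected by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    sim = SimulationConfig(**d.pop("simulation", {}))
    filt = FilterConfig(**d.pop("filters", {}))
    if "sex_stratified_cohorts" in d:
        d["sex_stratified_cohorts"] = tuple(d["sex_stratified_cohorts"])
    cfg = PipelineConfig(simulation=sim, filters=filt, **d)
    cfg.validate()
    return cfg
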