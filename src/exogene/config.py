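"""Run and simulation configuration objects.

All tunable knobs of the pipeline and of the synthetic cohort generator live
here, with validation at construction time.  Configurations round-trip
through YAML so a whole analysis is reproducible from a single file plus a
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SimulationConfig",
    "RunConfig",
    "ExposureWindow",
    "ClusterDefinition",
    "InvalidConfigError",
    "load_yaml",
]


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


# Default fixed-effect coefficients for the longitudinal UPDRS-III model
# (points of motor score per unit of covariate; visit is the mean
# progression per visit).
_DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 12.0,
    "visit": 1.5,
    "age_at_diagnosis": 0.10,
    "male": 1.0,
    "hispanic": 2.0,
    "pd_duration_baseline": 0.8,
    "family_history": 0.5,
    "education_years": -0.15,
    "study_wave": 1.0,
}


@dataclass(frozen=True)
class ExposureWindow:
    """Exposure accrual window: records start in ``start_year`` and the
    per-subject window ends ``lag_years`` before diagnosis (prodromal lag)."""

    start_year: int = 1974
    lag_years: int = 10

    def __post_init__(self) -> None:
        if self.lag_years < 0:
            raise InvalidConfigError("lag_years must be >= 0")

    def end_year(self, diagnosis_year: int) -> int:
        return diagnosis_year - self.lag_years


@dataclass
class ClusterDefinition:
    """A co-application pesticide cluster with per-pesticide PD log-odds
    weights (betas) used in the weighted exposure sum."""

    cluster_id: str
    members: list[str]
    beta_weights: dict[str, float] | None = None

    def require_betas(self) -> dict[str, float]:
        if self.beta_weights is None:
            raise InvalidConfigError(
                f"cluster {self.cluster_id} has no beta weights"
            )
        missing = [m for m in self.members if m not in self.beta_weights]
        if missing:
            raise InvalidConfigError(
                f"cluster {self.cluster_id} missing betas for {missing}"
            )
        return self.beta_weights


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the PEG study shape: 757 PD patients in two
    self-reported ancestry strata, up to three UPDRS-III visits, an
    85-gene panel in five selection groups, ambient pesticide application
    records since 1974 with a correlated 10-pesticide "cotton" cluster,
    and a handful of planted enriched variants whose carriers are biased
    toward high exposure and fast progression.
    """

    n_subjects: int = 757
    subpop_fractions: dict[str, float] = field(
        default_factory=lambda: {"European": 0.83, "Hispanic": 0.17}
    )
    n_visits_max: int = 3
    dropout_retain_prob: float = 0.7
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FIXED_EFFECTS)
    )
    slope_sd: float = 3.0
    intercept_sd: float = 8.0
    resid_sd: float = 2.0

    # pesticide applications
    n_pesticides: int = 30
    n_clusters: int = 3
    cotton_cluster_size: int = 10
    within_cluster_corr: float = 0.6
    zero_exposure_fraction: float = 0.05
    workplace_zero_fraction: float = 0.4
    application_prob: float = 0.7

    # variant panel
    n_panel_genes: int = 85
    group_sizes: tuple[int, ...] = (14, 13, 18, 36, 4)
    n_background_variants: int = 300
    n_planted_variants: int = 30
    enrichment_fold: float = 8.0
    exposure_progression_bias: float = 1.5
    reference_absent_fraction: float = 0.1
    mean_depth: float = 80.0
    low_depth_fraction: float = 0.03
    fail_filter_fraction: float = 0.02
    low_qual_fraction: float = 0.02

    # relatedness
    n_related_pairs: int = 2
    n_relatedness_sites: int = 20000

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidConfigError("n_subjects must be positive")
        total = sum(self.subpop_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise InvalidConfigError(
                f"subpop_fractions must sum to 1 (got {total})"
            )
        if sum(self.group_sizes) != self.n_panel_genes:
            raise InvalidConfigError(
                "group_sizes must sum to n_panel_genes "
                f"({sum(self.group_sizes)} != {self.n_panel_genes})"
            )
        for name in ("slope_sd", "intercept_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.within_cluster_corr < 1.0:
            raise InvalidConfigError("within_cluster_corr must be in [0, 1)")
        if self.enrichment_fold < 1.0:
            raise InvalidConfigError("enrichment_fold must be >= 1")
        if self.enrichment_fold == 1.0 and self.n_planted_variants > 0:
            raise InvalidConfigError(
                "enrichment_fold == 1 only valid with n_planted_variants == 0 "
                "(null simulation)"
            )
        if self.exposure_progression_bias < 0:
            raise InvalidConfigError("exposure_progression_bias must be >= 0")
        if self.cotton_cluster_size > self.n_pesticides:
            raise InvalidConfigError("cotton cluster larger than panel")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunConfig:
    """End-to-end pipeline settings (thresholds, window, alpha, paths)."""

    window: ExposureWindow = field(default_factory=ExposureWindow)
    cluster_cutpoint: float = 0.45
    alpha: float = 0.05
    ibd_threshold: float = 0.05
    min_visits_for_score: int = 2
    exposure_min: float = 1.0
    progression_min: float = 1.0
    min_site_quality: float = 30.0
    min_depth: int = 10
    min_depth_fraction: float = 0.9
    population_map: dict[str, str] = field(
        default_factory=lambda: {
            "European": "nfe",
            "Hispanic": "amr",
        }
    )

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "window" in d and isinstance(d["window"], Mapping):
            d["window"] = ExposureWindow(**d["window"])
        return cls(**d)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def simulation_config_from_yaml(path) -> SimulationConfig:
    d = load_yaml(path)
    if "group_sizes" in d:
        d["group_sizes"] = tuple(d["group_sizes"])
    return SimulationConfig(**d)


def run_config_from_yaml(path) -> RunConfig:
    return RunConfig.from_dict(load_yaml(path))
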