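"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Default marker panel: (family, n_markers, antigen_class, isotype,
#: log_transform, has_response_call). 56 markers total, 14 endemic-CoV,
#: mirroring the study panel's family structure (binding IgG1/IgG3/IgA,
#: MSD IgG, neutralization, functional antibody percents, B cells, T cells).
DEFAULT_FAMILIES: tuple[tuple[str, int, str, str, bool, bool], ...] = (
    ("igg1_bama", 6, "sars2", "IgG1", True, True),
    ("igg1_bama_endemic", 6, "endemic", "IgG1", True, False),
    ("igg3_bama", 6, "sars2", "IgG3", True, True),
    ("igg3_bama_endemic", 4, "endemic", "IgG3", True, False),
    ("iga_bama", 4, "sars2", "IgA", True, True),
    ("iga_bama_endemic", 4, "endemic", "IgA", True, False),
    ("msd_igg", 4, "sars2", "IgG", True, True),
    ("neutralization", 2, "sars2", "NA", True, True),
    ("functional", 6, "sars2", "NA", False, True),
    ("bcell", 8, "sars2", "NA", True, True),
    ("tcell", 6, "sars2", "NA", True, True),
)

SEVERITIES = ("asymptomatic", "symptomatic", "hospitalized")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the study conditions: 216 PWOH and 43 PLWH, three COVID-19
    severity strata at the observed cohort proportions, 56 markers in
    assay-family blocks, 13-131 days since diagnosis, and Table-1-like
    covariate imbalances (more males and more smokers among PLWH).
    """

    n_pwoh: int = 216
    n_plwh: int = 43
    #: (asymptomatic, symptomatic outpatient, hospitalized); cohort-wide
    #: proportions 59/101/99 out of 259.
    severity_props: tuple[float, float, float] = (59 / 259, 101 / 259, 99 / 259)
    n_markers: int = 56
    block_sizes: Sequence[int] | None = None
    #: Within-assay-family latent-factor correlation per HIV group; the PLWH
    #: default is lower to emulate weaker coordination of responses.
    within_block_rho: Mapping[str, float] = field(
        default_factory=lambda: {"PWOH": 0.5, "PLWH": 0.25}
    )
    #: {marker_index: {"all" | severity: log-GMR}} added to PLWH log-means.
    marker_effects: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    #: log-scale coefficients of the confounders, applied to every marker.
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.005,
            "sex_male": 0.10,
            "region_us": 0.10,
            "smoking": 0.05,
            "days_since_dx": -0.003,
        }
    )
    days_range: tuple[int, int] = (13, 131)
    missing_rate: float = 0.02
    #: Covariate-generation probabilities; defaults echo Table 1.
    male_prob: Mapping[str, float] = field(
        default_factory=lambda: {"PWOH": 0.50, "PLWH": 0.837}
    )
    smoking_prob: Mapping[str, float] = field(
        default_factory=lambda: {"PWOH": 0.088, "PLWH": 0.302}
    )
    us_prob: Mapping[str, float] = field(
        default_factory=lambda: {"PWOH": 0.49, "PLWH": 0.69}
    )
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"PWOH": (49.0, 15.22), "PLWH": (45.8, 13.21)}
    )
    marker_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            sizes = [n for _, n, *_ in DEFAULT_FAMILIES]
            if sum(sizes) == self.n_markers:
                self.block_sizes = sizes
            else:  # split evenly into blocks of ~7 for non-default panels
                n_blocks = max(1, round(self.n_markers / 7))
                base = self.n_markers // n_blocks
                sizes = [base] * n_blocks
                for i in range(self.n_markers - base * n_blocks):
                    sizes[i] += 1
                self.block_sizes = sizes
        self.validate()

    def validate(self) -> None:
        if self.n_pwoh < 1 or self.n_plwh < 1:
            raise ConfigurationError("group sizes must be positive")
        if len(self.severity_props) != 3 or not np.isclose(
            sum(self.severity_props), 1.0
        ):
            raise ConfigurationError("severity_props must be 3 proportions summing to 1")
        if any(p < 0 for p in self.severity_props):
            raise ConfigurationError("severity_props must be nonnegative")
        if sum(self.block_sizes) != self.n_markers:
            raise ConfigurationError(
                f"block_sizes sum {sum(self.block_sizes)} != n_markers {self.n_markers}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for g, r in dict(self.within_block_rho).items():
            if not -1 < r < 1:
                raise ConfigurationError(f"within_block_rho[{g}] must be in (-1, 1)")
        lo, hi = self.days_range
        if lo > hi:
            raise ConfigurationError("days_range must be an increasing interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_effects"] = {
            str(k): dict(v) for k, v in dict(self.marker_effects).items()
        }
        return d


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    output_dir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    covariates: tuple[str, ...] = (
        "age", "sex_male", "region_us", "smoking", "days_since_dx",
    )
    corr_deselect_threshold: float = 0.95
    impute_iterations: int = 10
    fdr: float = 0.10
    rho_min: float = 0.70
    sig_p: float = 0.05
    sig_q: float = 0.20
    n_subsamples: int = 10_000
    n_permutations: int = 1000
    rfe_repeats: int = 200
    rfe_threshold: float = 0.90
    backward_repeats: int = 30
    k_folds: int = 10
    seed: int | None = None
    run_classifier: bool = False

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is required for every stochastic stage")
        for name in ("corr_deselect_threshold", "fdr", "rho_min", "sig_p", "sig_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        self.simulation.validate()
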