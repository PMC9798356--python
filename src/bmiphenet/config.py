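"""Simulation and pipeline configuration objects.

The simulator emulates a biobank-style cohort: additive polygenic BMI with a
target heritability, covariates (age, sex, ten genotype principal
components), and binary disease phenotypes ("phecodes") whose log-odds
depend on standardized BMI plus block-structured latent comorbidity factors.
Defaults mirror the demographic structure of a large veteran biobank
(predominantly male, mean age ~64, mean BMI ~29.9 kg/m^2) and per-SD disease
odds ratios typical of phenome-wide BMI studies.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import yaml

__all__ = [
    "PhecodeSpec",
    "SimulationConfig",
    "TwoSampleConfig",
    "PipelineConfig",
    "default_phecode_panel",
]


@dataclass
class PhecodeSpec:
    """Generative description of one binary disease code.

    Parameters
    ----------
    code : dotted phecode string, e.g. ``"250.2"``.
    baseline_prevalence : P(case) at BMI_std = 0 with all loadings zero.
    gamma_bmi : log odds ratio per SD of BMI (the causal effect the MR
        stage should recover).
    community_block : label of the latent comorbidity block this code
        belongs to; codes sharing a block share one standard-normal factor
        per individual.
    latent_loading : coefficient of the shared block factor on the logit.
    confounder_loading : coefficient of the unmeasured confounder U on the
        logit (U also shifts BMI via ``SimulationConfig.confounder_bmi_effect``);
        used to study observational vs genetic estimates under confounding.
    """

    code: str
    baseline_prevalence: float
    gamma_bmi: float = 0.0
    community_block: str = "none"
    latent_loading: float = 0.0
    confounder_loading: float = 0.0
    description: str = ""
    disease_group: str = ""

    def validate(self) -> None:
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError(
                f"phecode {self.code}: baseline_prevalence must be in (0,1), "
                f"got {self.baseline_prevalence}"
            )
        parts = self.code.split(".")
        if not parts[0].isdigit() or (len(parts) == 2 and not parts[1].isdigit()) or len(parts) > 2:
            raise ValueError(f"phecode {self.code!r} does not parse as <integer>[.<digits>]")


def default_phecode_panel() -> list[PhecodeSpec]:
    """A small realistic disease panel.

    Per-SD odds ratios follow the magnitudes reported for BMI in
    phenome-wide MR studies (T2DM ~2.6, sleep apnea ~2.4, hypertension
    ~2.2, ischemic heart disease ~1.7, asthma ~1.25, protective inguinal
    hernia ~0.58 and osteoporosis ~0.64); prevalences are plausible for an
    older, mostly male clinical cohort. Blocks group codes that co-occur.
    """
    L = math.log
    return [
        PhecodeSpec("250.2", 0.25, L(2.64), "cardiometabolic", 1.2, description="Type 2 diabetes", disease_group="Endocrine/metabolic"),
        PhecodeSpec("401", 0.45, L(2.20), "cardiometabolic", 1.2, description="Hypertension", disease_group="Circulatory system"),
        PhecodeSpec("411", 0.20, L(1.67), "cardiometabolic", 1.2, description="Ischemic heart disease", disease_group="Circulatory system"),
        PhecodeSpec("428.1", 0.08, L(2.26), "cardiometabolic", 1.2, description="Congestive heart failure NOS", disease_group="Circulatory system"),
        PhecodeSpec("327.3", 0.15, L(2.36), "respiratory", 1.2, description="Sleep apnea", disease_group="Neurological"),
        PhecodeSpec("495", 0.08, L(1.25), "respiratory", 1.2, description="Asthma", disease_group="Respiratory"),
        PhecodeSpec("509.1", 0.03, L(1.85), "respiratory", 1.2, description="Respiratory failure", disease_group="Respiratory"),
        PhecodeSpec("740.9", 0.30, L(1.61), "musculoskeletal", 1.2, description="Osteoarthrosis NOS", disease_group="Musculoskeletal"),
        PhecodeSpec("716.9", 0.12, L(1.45), "musculoskeletal", 1.2, description="Arthropathy NOS", disease_group="Musculoskeletal"),
        PhecodeSpec("720.1", 0.07, L(1.46), "musculoskeletal", 1.2, description="Spinal stenosis of lumbar region", disease_group="Musculoskeletal"),
        PhecodeSpec("550.1", 0.06, L(0.58), "none", 0.0, description="Inguinal hernia", disease_group="Digestive"),
        PhecodeSpec("743.1", 0.05, L(0.64), "none", 0.0, description="Osteoporosis", disease_group="Musculoskeletal"),
    ]


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort. ``seed`` fully determines
    every emitted array."""

    n_individuals: int = 5000
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 200
    h2_bmi: float = 0.188
    bmi_mean: float = 29.88
    bmi_sd: float = 5.86
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.10, "sex": 0.10}
    )
    phecode_spec: list[PhecodeSpec] = field(default_factory=default_phecode_panel)
    phecode_covariate_effects: dict[str, float] = field(default_factory=dict)
    n_latent_factors: int | None = None
    ld_block_size: int = 10
    ld_rho: float = 0.3
    seed: int = 0
    # demographics (Table-style biobank defaults)
    male_fraction: float = 0.93
    age_mean: float = 63.95
    age_sd: float = 13.11
    # unmeasured confounder: adds confounder_bmi_effect * U to standardized BMI
    confounder_bmi_effect: float = 0.0
    # variant coordinates
    variants_per_chrom: int = 2000
    variant_spacing: int = 20_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.h2_bmi < 1.0):
            raise ValueError(f"h2_bmi must be in [0,1), got {self.h2_bmi}")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0,1), got {self.ld_rho}")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must be in [0,1]")
        if self.h2_bmi + self.confounder_bmi_effect**2 >= 1.0:
            raise ValueError("h2_bmi + confounder_bmi_effect^2 must stay below 1")
        specs = []
        for ph in self.phecode_spec:
            if isinstance(ph, dict):
                ph = PhecodeSpec(**ph)
            ph.validate()
            specs.append(ph)
        self.phecode_spec = specs
        if self.n_latent_factors is None:
            self.n_latent_factors = len(
                {p.community_block for p in self.phecode_spec if p.community_block != "none"}
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "phecode_spec" in d:
            d["phecode_spec"] = [
                p if isinstance(p, PhecodeSpec) else PhecodeSpec(**p) for p in d["phecode_spec"]
            ]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class TwoSampleConfig:
    """Generator settings for two-sample MR summary statistics.

    Outcome betas follow ``beta_causal * beta_exposure + alpha_j + noise``
    where ``alpha_j`` is the pleiotropic (direct) effect: zero for valid
    instruments, mean-zero Gaussian under ``balanced`` pleiotropy, a
    constant ``pleiotropy_delta`` under ``directional``.
    """

    n_variants: int = 100
    beta_causal: float = 0.1
    pleiotropy_mode: str = "none"  # none | balanced | directional
    frac_invalid: float = 0.0
    pleiotropy_delta: float = 0.05  # directional: constant direct effect
    pleiotropy_sd: float = 0.05  # balanced: sd of mean-zero direct effects
    exposure_beta_sd: float = 0.05  # sd of true exposure effects
    se_exposure: float = 0.005
    se_outcome: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in {"none", "balanced", "directional"}:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0.0 <= self.frac_invalid < 1.0):
            raise ValueError("frac_invalid must be in [0,1)")
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError("SEs must be positive")


@dataclass
class PipelineConfig:
    """Thresholds and paths for the end-to-end pipeline run.

    Defaults are the conventional analysis thresholds: genome-wide
    significance 5e-8, clumping r^2 < 0.1 within 500 kb loci, >=200 cases
    and >=200 controls per phecode, comorbidity edges at phi >= 0.2 with
    adjusted p < 0.05.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    locus_window: int = 500_000
    min_cases: int = 200
    min_controls: int = 200
    phi_min: float = 0.2
    alpha: float = 0.05
    adjust_method: str = "bh"
    n_null: int = 200
    seed: int = 0
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1) or not (0 <= self.r2_threshold <= 1):
            raise ValueError("thresholds out of domain")
        if self.adjust_method not in {"bh", "bonferroni"}:
            raise ValueError("adjust_method must be 'bh' or 'bonferroni'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
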