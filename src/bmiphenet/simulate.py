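"""Synthetic cohort generator.

Emulates the statistical structure a genotype-to-phenome BMI analysis
assumes, so every downstream stage (GWAS, meta-analysis, clumping, genetic
risk score, PheWAS, Mendelian randomization, comorbidity network) can be
exercised and validated without access to any real biobank:

* genotypes: Hardy-Weinberg dosages with block LD induced by a Gaussian
  copula on the haplotype level;
* BMI: additive polygenic score with a target heritability, plus covariate
  effects, an optional unmeasured confounder, and Gaussian environment;
* phecodes: Bernoulli given a logistic linear predictor in standardized
  BMI, a shared per-block latent comorbidity factor, the confounder, and
  optional covariate terms;
* two-sample summary statistics with controllable pleiotropy for the MR
  sensitivity estimators.

All draws come from named substreams of one master seed (see ``_rng``), so
output is bit-reproducible and adding a phecode does not perturb genotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._rng import substream
from .config import SimulationConfig, TwoSampleConfig
from .datatypes import GenotypeMatrix, PhecodeTable

__all__ = [
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_bmi",
    "simulate_phecodes",
    "simulate_two_sample",
    "simulate_cohort",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "T"), ("G", "A")]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an additive dosage matrix with block LD.

    Each variant's two alleles are Bernoulli(eaf) (Hardy-Weinberg); within
    each block of ``ld_block_size`` consecutive variants the two haplotype
    draws share a latent equicorrelated Gaussian (correlation ``ld_rho``),
    i.e. a Gaussian copula, which induces positive dosage LD inside blocks
    and independence across blocks.
    """
    rng = substream(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    eaf = rng.uniform(lo, hi, size=m)
    thresh = norm.ppf(eaf)  # latent z < thresh -> effect allele

    rho = config.ld_rho
    bs = max(1, config.ld_block_size)
    dosages = np.zeros((n, m), dtype=np.float64)
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        if rho > 0:
            n_blocks = (m + bs - 1) // bs
            f = rng.standard_normal((n, n_blocks))
            block_of = np.arange(m) // bs
            z = np.sqrt(rho) * f[:, block_of] + np.sqrt(1.0 - rho) * z
        dosages += (z < thresh[None, :]).astype(np.float64)

    variants = _variant_metadata(config, eaf, rng)
    return GenotypeMatrix(dosages=dosages, variants=variants)


def _variant_metadata(config: SimulationConfig, eaf: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    m = len(eaf)
    idx = np.arange(m)
    chrom = 1 + idx // config.variants_per_chrom
    pos = 1 + (idx % config.variants_per_chrom) * config.variant_spacing
    pairs = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[k][0] for k in pairs]
    oa = [_ALLELE_PAIRS[k][1] for k in pairs]
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in idx],
            "chr": chrom.astype(int),
            "pos": pos.astype(int),
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
        }
    )


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age, age^2, sex and ten principal-component scores.

    Age is normal (clipped to a plausible adult range), sex Bernoulli with
    the configured male fraction, and PCs independent standard normals
    centered to mean zero (the analysis consumes PCs as given covariates;
    it never computes them from genotypes).
    """
    rng = substream(config.seed, "covariates")
    n = config.n_individuals
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 19, 104)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    pcs = rng.standard_normal((n, 10))
    pcs -= pcs.mean(axis=0, keepdims=True)
    cov = pd.DataFrame({"age": age, "age2": age**2, "sex": sex})
    for k in range(10):
        cov[f"pc{k + 1}"] = pcs[:, k]
    cov.index = [f"id{i:06d}" for i in range(n)]
    return cov


def _standardized_covariate_columns(covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariates on a unit scale for use as generative effects: age and
    PCs z-scored, sex centered to mean zero (male = +)."""
    out = pd.DataFrame(index=covariates.index)
    for name in covariates.columns:
        if name == "sex":
            x = (covariates["sex"] == "male").astype(float)
            out["sex"] = x - x.mean()
        else:
            x = covariates[name].astype(float)
            sd = x.std(ddof=0)
            out[name] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return out


def _confounder(config: SimulationConfig) -> np.ndarray:
    rng = substream(config.seed, "confounder")
    return rng.standard_normal(config.n_individuals)


def simulate_bmi(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Additive polygenic BMI.

    On the standardized (unit-variance, covariate-free) scale:
    ``z = g + c + confounder_bmi_effect*U + e`` where the genetic value
    ``g = sum_j beta_j (dosage_j - 2 eaf_j)`` is rescaled so its realized
    variance equals ``h2_bmi`` exactly, ``c`` is the configured covariate
    contribution, and ``e`` is Gaussian with variance
    ``1 - h2_bmi - confounder_bmi_effect^2``. The trait is then placed on
    the kg/m^2 scale as ``bmi = bmi_mean + bmi_sd * z``.

    Returns the trait table and the true per-dosage causal effects (on the
    standardized scale, indexed by variant id; zero for non-causal variants).
    """
    if not (0.0 <= config.h2_bmi < 1.0):
        raise ValueError("h2_bmi must be in [0,1)")
    rng = substream(config.seed, "bmi")
    n, m = genotypes.dosages.shape

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    raw = rng.standard_normal(config.n_causal)
    centered = genotypes.dosages[:, causal_idx] - 2.0 * genotypes.variants["eaf"].to_numpy()[causal_idx]
    g_raw = centered @ raw
    sd_raw = g_raw.std(ddof=0)
    if config.h2_bmi > 0 and sd_raw > 0:
        scale = np.sqrt(config.h2_bmi) / sd_raw
    else:
        scale = 0.0
    g = g_raw * scale

    betas = np.zeros(m)
    betas[causal_idx] = raw * scale
    true_betas = pd.Series(betas, index=genotypes.variants["snp"].to_numpy(), name="beta_true")

    std_cov = _standardized_covariate_columns(covariates)
    c = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        if name not in std_cov.columns:
            raise KeyError(f"covariate_effects names unknown covariate {name!r}")
        c += eff * std_cov[name].to_numpy()

    u = config.confounder_bmi_effect * _confounder(config)
    e_var = 1.0 - config.h2_bmi - config.confounder_bmi_effect**2
    e = rng.normal(0.0, np.sqrt(e_var), size=n)

    z = g + c + u + e
    bmi = config.bmi_mean + config.bmi_sd * z
    bmi = np.maximum(bmi, 10.0)  # physical floor; kg/m^2 must stay positive
    trait = pd.DataFrame({"bmi": bmi}, index=covariates.index)
    return trait, true_betas


def simulate_phecodes(
    trait: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> PhecodeTable:
    """Draw binary disease statuses from the logistic liability chain.

    For each phecode: ``logit P(case) = logit(prev) + gamma_bmi*BMI_std +
    latent_loading*F_block + confounder_loading*U + covariate terms`` with
    statuses conditionally independent given the linear predictor. F_block
    is one standard-normal factor per individual shared by all phecodes of
    the same community block — the mechanism that makes codes co-occur and
    gives the comorbidity network its planted structure.
    """
    if not config.phecode_spec:
        raise ValueError("phecode_spec must be nonempty")
    rng = substream(config.seed, "phecodes")
    n = len(trait)
    bmi = trait["bmi"].to_numpy()
    bmi_std = (bmi - bmi.mean()) / bmi.std(ddof=1)

    blocks = sorted({p.community_block for p in config.phecode_spec if p.community_block != "none"})
    factors = {b: rng.standard_normal(n) for b in blocks}
    u = _confounder(config)

    std_cov = _standardized_covariate_columns(covariates)
    cov_term = np.zeros(n)
    for name, eff in config.phecode_covariate_effects.items():
        cov_term += eff * std_cov[name].to_numpy()

    status = {}
    meta_rows = []
    for ph in config.phecode_spec:
        lp = logit(ph.baseline_prevalence) + ph.gamma_bmi * bmi_std + cov_term
        if ph.community_block != "none" and ph.latent_loading != 0.0:
            lp = lp + ph.latent_loading * factors[ph.community_block]
        if ph.confounder_loading != 0.0:
            lp = lp + ph.confounder_loading * u
        status[ph.code] = (rng.random(n) < expit(lp)).astype(np.int8)
        meta_rows.append(
            {"code": ph.code, "description": ph.description, "disease_group": ph.disease_group}
        )

    status_df = pd.DataFrame(status, index=trait.index)
    meta = pd.DataFrame(meta_rows)
    return PhecodeTable(status=status_df, meta=meta)


def simulate_two_sample(config: TwoSampleConfig) -> pd.DataFrame:
    """Two-sample MR summary statistics with controllable pleiotropy.

    Columns: snp, beta_exp, se_exp, beta_out, se_out, plus generator truth
    (beta_causal, alpha = per-variant direct effect, invalid flag).
    True exposure effects are half-normal (|N(0, exposure_beta_sd^2)| plus a
    small floor so every instrument is relevant); observed betas add
    Gaussian noise at the stated SEs.
    """
    rng = substream(config.seed, "two_sample")
    m = config.n_variants
    bx_true = np.abs(rng.normal(0.0, config.exposure_beta_sd, size=m)) + 0.01

    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    if config.pleiotropy_mode != "none" and config.frac_invalid > 0:
        k = int(round(config.frac_invalid * m))
        invalid[rng.choice(m, size=k, replace=False)] = True
        if config.pleiotropy_mode == "directional":
            alpha[invalid] = config.pleiotropy_delta
        else:  # balanced
            alpha[invalid] = rng.normal(0.0, config.pleiotropy_sd, size=invalid.sum())

    beta_exp = bx_true + rng.normal(0.0, config.se_exposure, size=m)
    beta_out = config.beta_causal * bx_true + alpha + rng.normal(0.0, config.se_outcome, size=m)
    return pd.DataFrame(
        {
            "snp": [f"iv{i + 1:04d}" for i in range(m)],
            "beta_exp": beta_exp,
            "se_exp": np.full(m, config.se_exposure),
            "beta_out": beta_out,
            "se_out": np.full(m, config.se_outcome),
            "beta_exp_true": bx_true,
            "alpha": alpha,
            "invalid": invalid,
        }
    )


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, covariates, (trait, true betas),
    phecodes — the full cohort in one call."""
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    trait, true_betas = simulate_bmi(genotypes, covariates, config)
    phecodes = simulate_phecodes(trait, covariates, config)
    return genotypes, covariates, trait, true_betas, phecodes
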