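"""Weighted genetic risk score (GRS) construction and instrument strength.

The GRS is the weighted sum of effect-allele dosages over the independent
genome-wide-significant variants, with weights taken from an external
association source (external weights avoid winner's-curse overfitting when
the score is used as an instrument in the same cohort that discovered the
variants).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, LocusSet

logger = logging.getLogger(__name__)

__all__ = ["build_weights", "compute_grs", "variance_explained", "first_stage_f"]


def build_weights(loci: LocusSet, external: pd.DataFrame) -> pd.DataFrame:
    """One weight per independent SNP found in the external source.

    The external beta is aligned to the SNP's own effect allele (an exact
    effect/other swap flips the sign); SNPs absent from the external source
    or with irreconcilable alleles are dropped with a logged count.
    Returns a DataFrame with columns snp, ea, weight.
    """
    ext = external.set_index("snp")
    rows = []
    dropped = 0
    for rec in loci.accepted.itertuples(index=False):
        if rec.snp not in ext.index:
            dropped += 1
            continue
        e = ext.loc[rec.snp]
        if (e["ea"], e["oa"]) == (rec.ea, rec.oa):
            w = float(e["beta"])
        elif (e["ea"], e["oa"]) == (rec.oa, rec.ea):
            w = -float(e["beta"])
        else:
            dropped += 1
            continue
        rows.append({"snp": rec.snp, "ea": rec.ea, "weight": w})
    if dropped:
        logger.info("build_weights: %d independent SNPs absent/unharmonizable in external source", dropped)
    return pd.DataFrame(rows, columns=["snp", "ea", "weight"])


def compute_grs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """grs_i = sum_j w_j * dosage_ij after allele alignment.

    When a weight's effect allele is the variant's other allele the dosage
    is counted on the opposite strand of effects, i.e. replaced by
    2 - dosage. A weight whose variant is missing from the panel is an
    error (the score would silently change meaning).
    """
    if len(weights) == 0:
        return np.zeros(genotypes.n_individuals)
    vmeta = genotypes.variants.set_index("snp")
    missing = [s for s in weights["snp"] if s not in vmeta.index]
    if missing:
        raise KeyError(f"weights reference variants absent from genotypes: {missing[:10]}")
    D = genotypes.columns(weights["snp"].tolist()).astype(float)
    w = weights["weight"].to_numpy(dtype=float)
    flip = np.array(
        [vmeta.loc[s, "ea"] != ea for s, ea in zip(weights["snp"], weights["ea"])], dtype=bool
    )
    if flip.any():
        D = D.copy()
        D[:, flip] = 2.0 - D[:, flip]
    return D @ w


def variance_explained(
    score: np.ndarray,
    trait: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    incremental: bool = True,
) -> float:
    """Proportion of trait variance explained by the score.

    Default is the incremental R^2: R^2(bmi ~ covariates + score) -
    R^2(bmi ~ covariates), with covariates age, age^2, sex, pc1..pc10.
    ``incremental=False`` (or no covariates) gives the plain univariate R^2.
    Returns 0.0 for a constant score.
    """
    y = trait["bmi"].to_numpy(dtype=float)
    s = np.asarray(score, dtype=float)
    if s.std(ddof=0) == 0:
        return 0.0

    def _r2(X: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float((resid**2).sum()) / tss

    ones = np.ones(len(y))
    if covariates is None or not incremental:
        return max(_r2(np.column_stack([ones, s])), 0.0)
    names = ["age", "age2"] + [f"pc{k}" for k in range(1, 11)]
    cols = [covariates[c].to_numpy(dtype=float) for c in names]
    cols.append((covariates["sex"] == "male").to_numpy(dtype=float))
    X0 = np.column_stack([ones] + cols)
    X1 = np.column_stack([X0, s])
    return max(_r2(X1) - _r2(X0), 0.0)


def first_stage_f(score: np.ndarray, trait: pd.DataFrame) -> float:
    """F statistic of the simple regression BMI ~ GRS (instrument relevance)."""
    s = np.asarray(score, dtype=float)
    y = trait["bmi"].to_numpy(dtype=float)
    n = len(y)
    sc = s - s.mean()
    yc = y - y.mean()
    sxx = float(sc @ sc)
    if sxx == 0:
        return 0.0
    beta = float(sc @ yc) / sxx
    sse = float(yc @ yc) - beta * float(sc @ yc)
    if sse <= 0:
        return float("inf")
    return beta**2 * sxx / (sse / (n - 2))
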