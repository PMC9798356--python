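"""Single-variant association, meta-analysis, clumping and locus calling.

The association chain follows the standard two-step quantitative-trait
recipe for large biobanks: within each sex stratum the trait is residualized
on age, age-squared and ten principal components; the pooled residuals are
mapped to normal scores by the rank-based inverse normal transform; each
variant is then tested by simple linear regression of the transformed
residuals on dosage under an additive model. Studies are combined by
inverse-variance-weighted fixed-effects meta-analysis, and independent
signals are selected by greedy p-value-ordered clumping at r^2 < 0.1 with
500 kb locus windows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ASSOC_COLUMNS, GenotypeMatrix, Locus, LocusSet

logger = logging.getLogger(__name__)

__all__ = [
    "residualize_trait",
    "inverse_normal_transform",
    "run_gwas",
    "meta_analyze",
    "select_independent_snps",
    "annotate_novelty",
    "genomic_control_lambda",
]

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.1
LOCUS_WINDOW = 500_000
_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549364...


def residualize_trait(
    trait: pd.DataFrame, covariates: pd.DataFrame, covariate_names: tuple[str, ...] | None = None
) -> np.ndarray:
    """Sex-stratified OLS residuals of BMI on age, age^2 and pc1..pc10.

    Residuals are returned in the input row order (strata are fitted
    separately, not reordered). Raises if a stratum's design matrix is
    singular or has fewer than two rows.
    """
    if covariate_names is None:
        covariate_names = ("age", "age2") + tuple(f"pc{k}" for k in range(1, 11))
    y = trait["bmi"].to_numpy(dtype=float)
    resid = np.full_like(y, np.nan)
    sex = covariates["sex"].to_numpy()
    for stratum in pd.unique(sex):
        mask = sex == stratum
        if mask.sum() < 2:
            raise ValueError(f"sex stratum {stratum!r} has fewer than 2 individuals")
        X = np.column_stack(
            [np.ones(mask.sum())] + [covariates.loc[mask, c].to_numpy(dtype=float) for c in covariate_names]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"singular covariate design in sex stratum {stratum!r}")
        coef, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
        resid[mask] = y[mask] - X @ coef
    return resid


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (Blom) scores.

    value_i -> Phi^{-1}((r_i - 3/8) / (n + 1/4)) with average ranks for
    ties; preserves rank order and yields approximately standard-normal
    output.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D array with at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values cannot be rank-transformed")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def run_gwas(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    skip_monomorphic: bool = True,
    use_t: str = "auto",
) -> pd.DataFrame:
    """Per-variant simple linear regression of ``y`` on dosage.

    Vectorized closed-form OLS with intercept: for variant j,
    beta_j = S_xy/S_xx, se_j = sqrt((S_yy - beta_j S_xy)/(n-2)/S_xx).
    Two-sided p from the normal approximation (default for n >= 100; exact
    t reference when ``use_t='auto'`` and n < 100, or ``use_t='always'``).
    Monomorphic variants are skipped with a logged count (``skip_monomorphic
    =False`` emits them with beta=0, se=nan and a ``monomorphic`` flag).
    """
    y = np.asarray(y, dtype=float)
    n, m = genotypes.dosages.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.shape}, expected ({n},)")
    if y.std(ddof=0) == 0:
        raise ValueError("zero-variance phenotype")

    G = genotypes.dosages
    gbar = G.mean(axis=0)
    yc = y - y.mean()
    sxx = ((G - gbar) ** 2).sum(axis=0)
    sxy = (G * yc[:, None]).sum(axis=0)
    syy = float(yc @ yc)

    mono = sxx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        sse = syy - beta * sxy
        sigma2 = np.maximum(sse, 0.0) / (n - 2)
        se = np.sqrt(np.where(mono, np.nan, sigma2 / np.where(mono, 1.0, sxx)))
        z = beta / se

    if use_t == "always" or (use_t == "auto" and n < 100):
        p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # cap underflow away from exact 0

    out = genotypes.variants[["snp", "chr", "pos", "ea", "oa", "eaf"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    if mono.any():
        logger.info("run_gwas: %d monomorphic variants", int(mono.sum()))
        if skip_monomorphic:
            out = out.loc[~mono].reset_index(drop=True)
        else:
            out["monomorphic"] = mono
    return out


def meta_analyze(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    Records are matched by variant id; effect alleles are harmonized to the
    first study seen for each variant (an exact effect/other allele swap
    flips the beta sign and the frequency); records whose alleles cannot be
    reconciled by a swap are dropped with a logged reason. For each variant:
    beta = sum(b_i/se_i^2)/sum(1/se_i^2), se = sqrt(1/sum(1/se_i^2)),
    n summed, two-sided p from the normal approximation.
    """
    if not studies:
        raise ValueError("need at least one study")
    ref: dict[str, tuple] = {}
    acc: dict[str, dict] = {}
    dropped = 0
    for study in studies:
        for row in study.itertuples(index=False):
            snp = row.snp
            if snp not in ref:
                ref[snp] = (row.ea, row.oa, row.chr, row.pos)
                acc[snp] = {"w": 0.0, "wb": 0.0, "n": 0, "eaf_w": 0.0}
            ea, oa, _, _ = ref[snp]
            beta, eaf = row.beta, row.eaf
            if (row.ea, row.oa) == (ea, oa):
                pass
            elif (row.ea, row.oa) == (oa, ea):
                beta, eaf = -beta, 1.0 - eaf
            else:
                dropped += 1
                logger.info("meta_analyze: dropping %s (alleles %s/%s vs %s/%s)", snp, row.ea, row.oa, ea, oa)
                continue
            w = 1.0 / row.se**2
            a = acc[snp]
            a["w"] += w
            a["wb"] += w * beta
            a["n"] += int(row.n)
            a["eaf_w"] += w * eaf
    if dropped:
        logger.info("meta_analyze: dropped %d unharmonizable records", dropped)

    rows = []
    for snp, (ea, oa, chrom, pos) in ref.items():
        a = acc[snp]
        if a["w"] == 0:
            continue
        beta = a["wb"] / a["w"]
        se = np.sqrt(1.0 / a["w"])
        z = beta / se
        rows.append(
            {
                "snp": snp, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
                "eaf": a["eaf_w"] / a["w"], "beta": beta, "se": se,
                "p": max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny),
                "n": a["n"],
            }
        )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def _dosage_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    a = genotypes.column(snp_a)
    b = genotypes.column(snp_b)
    sa, sb = a.std(ddof=0), b.std(ddof=0)
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def select_independent_snps(
    assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = CLUMP_R2,
    locus_window: int = LOCUS_WINDOW,
) -> LocusSet:
    """Greedy LD clumping and locus formation.

    Significant variants (p < ``p_threshold``) are visited in ascending p
    (ties broken by chromosome then position); a variant is accepted iff its
    squared Pearson dosage correlation with every previously accepted
    variant is below ``r2_threshold``. Accepted variants within
    ``locus_window`` bp of each other on the same chromosome (chained) form
    one locus whose lead is the smallest-p member.
    """
    sig = assoc.loc[assoc["p"] < p_threshold].copy()
    if sig.empty:
        return LocusSet(loci=[], accepted=sig.reset_index(drop=True))
    sig = sig.sort_values(["p", "chr", "pos"], kind="mergesort").reset_index(drop=True)

    # standardized dosages of the significant set, so each LD check is one
    # dot product instead of a fresh correlation pass
    D = genotypes.columns(sig["snp"].tolist()).astype(float)
    D = D - D.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    D /= norms

    accepted_idx: list[int] = []
    for i in range(len(sig)):
        if accepted_idx:
            r = D[:, accepted_idx].T @ D[:, i]
            if np.any(r * r >= r2_threshold):
                continue
        accepted_idx.append(i)
    accepted = sig.iloc[accepted_idx].reset_index(drop=True)

    loci: list[Locus] = []
    by_pos = accepted.sort_values(["chr", "pos"], kind="mergesort")
    group: list[pd.Series] = []

    def _close(rows: list[pd.Series]) -> None:
        gdf = pd.DataFrame(rows)
        lead = gdf.loc[gdf["p"].idxmin()]
        secondaries = gdf.drop(index=lead.name)
        loci.append(
            Locus(
                lead=lead,
                secondaries=secondaries.reset_index(drop=True),
                chrom=int(lead["chr"]),
                start=int(gdf["pos"].min()),
                end=int(gdf["pos"].max()),
            )
        )

    for _, row in by_pos.iterrows():
        if group and (row["chr"] != group[-1]["chr"] or row["pos"] - group[-1]["pos"] > locus_window):
            _close(group)
            group = []
        group.append(row)
    if group:
        _close(group)
    loci.sort(key=lambda l: (l.chrom, l.start))
    return LocusSet(loci=loci, accepted=accepted)


def annotate_novelty(
    loci: LocusSet,
    known: list[tuple[int, int]],
    genotypes: GenotypeMatrix | None = None,
    known_snps: list[str] | None = None,
    distance: int = LOCUS_WINDOW,
    r2_threshold: float = CLUMP_R2,
) -> LocusSet:
    """Flag each locus novel iff its lead is more than ``distance`` bp from
    every known variant on the same chromosome; when a dosage panel and the
    known variants' ids are supplied, the lead must additionally show
    r^2 < ``r2_threshold`` with every same-chromosome known variant (a lead
    can tag a known signal through LD even beyond the distance window).
    """
    for locus in loci.loci:
        lead_pos = int(locus.lead["pos"])
        novel = all(
            chrom != locus.chrom or abs(lead_pos - pos) > distance for chrom, pos in known
        )
        if novel and genotypes is not None and known_snps is not None:
            for snp, (chrom, _pos) in zip(known_snps, known):
                if chrom == locus.chrom and _dosage_r2(genotypes, locus.lead["snp"], snp) >= r2_threshold:
                    novel = False
                    break
        locus.novel = novel
    return loci


def genomic_control_lambda(assoc: pd.DataFrame) -> float:
    """Median association chi-square divided by its null median (0.4549),
    the classic inflation diagnostic."""
    if len(assoc) == 0:
        raise ValueError("need at least one association record")
    z2 = (assoc["beta"] / assoc["se"]) ** 2
    return float(np.median(z2) / _CHI2_MEDIAN_1DF)
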