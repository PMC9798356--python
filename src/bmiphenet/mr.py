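"""Mendelian randomization estimators.

One-sample MR uses the genetic risk score as instrument: the ratio of the
outcome-on-score logistic coefficient to the exposure-on-score linear
coefficient gives the log-OR per SD of the exposure, with a first-order
delta-method standard error. Two-sample summary-data estimators — IVW,
Egger regression, and the weighted median — serve as sensitivity analyses
against pleiotropy: IVW is efficient when all instruments are valid, the
Egger intercept absorbs directional pleiotropy (under the InSIDE
assumption), and the weighted median is consistent while under half the
instrument weight is invalid.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._rng import substream
from .datatypes import MRResult, PhecodeTable
from .phewas import phewas_design

logger = logging.getLogger(__name__)

__all__ = ["grs_mr", "mr_ivw", "mr_egger", "mr_weighted_median", "wald_ratios"]

WEAK_INSTRUMENT_T = 10.0  # |b_X|/se_X below this attaches a warning flag


def _normal_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)


def grs_mr(
    score: np.ndarray,
    trait: pd.DataFrame,
    phecodes: PhecodeTable,
    covariates: pd.DataFrame,
    method: str = "ratio",
) -> list[MRResult]:
    """One-sample MR of every phecode using the GRS as instrument.

    Stage 1: OLS of standardized BMI on GRS + age + sex + pc1..pc10 gives
    b_X (SD of BMI per unit GRS). Stage 2 depends on ``method``:

    * ``"ratio"`` (default): logistic regression of each phecode on the
      same design gives b_Y (log-OR per unit GRS); the estimate is b_Y/b_X
      — the log-OR per SD of BMI — with delta-method SE se_Y/|b_X|. The
      logistic stage marginalizes over the BMI variance the score does not
      explain, so this targets a population-averaged odds ratio that is
      mildly attenuated relative to the conditional (liability-scale)
      effect — the standard non-collapsibility of the OR.
    * ``"2sri"``: two-stage residual inclusion — the first-stage residual
      enters the stage-2 logistic as an extra covariate, so the GRS
      coefficient targets the conditional log-OR; same ratio and delta SE.

    The first stage is treated as precisely estimated (with biobank n and a
    strong score its noise is negligible next to se_Y); a first-stage t
    below 10 attaches a weak-instrument warning.
    """
    from .phewas import standardize_bmi

    if method not in {"ratio", "2sri"}:
        raise ValueError(f"unknown one-sample MR method {method!r}")
    z_bmi = standardize_bmi(trait)
    s = np.asarray(score, dtype=float)
    Xc = phewas_design(covariates)
    X = np.column_stack([Xc[:, :1], s, Xc[:, 1:]])

    ols = sm.OLS(z_bmi, X).fit()
    b_x, se_x = float(ols.params[1]), float(ols.bse[1])
    t_x = abs(b_x) / se_x if se_x > 0 else 0.0
    weak = t_x < WEAK_INSTRUMENT_T
    if weak:
        logger.warning("grs_mr: weak instrument (first-stage t=%.2f < %.0f)", t_x, WEAK_INSTRUMENT_T)
    f_stat = t_x**2
    estimator = "grs_ratio" if method == "ratio" else "grs_2sri"
    X2 = X if method == "ratio" else np.column_stack([X, z_bmi - X @ np.asarray(ols.params)])

    results: list[MRResult] = []
    for code in phecodes.codes:
        y = phecodes.status[code].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X2).fit(disp=0, maxiter=100, method="newton", tol=1e-8)
                ok = bool(fit.mle_retvals.get("converged", True)) and np.all(np.isfinite(fit.bse))
            except (np.linalg.LinAlgError, ValueError):
                ok = False
        if not ok or b_x == 0:
            results.append(
                MRResult(outcome=code, estimator=estimator, beta=np.nan, se=np.nan,
                         p=np.nan, first_stage_f=f_stat, weak_instrument=weak, flagged=True)
            )
            continue
        b_y, se_y = float(fit.params[1]), float(fit.bse[1])
        beta = b_y / b_x
        se = se_y / abs(b_x)
        results.append(
            MRResult(outcome=code, estimator=estimator, beta=beta, se=se,
                     p=_normal_p(beta / se), first_stage_f=f_stat, weak_instrument=weak)
        )
    return results


def wald_ratios(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratio estimates beta_out/beta_exp and their first-order
    delta-method SEs se_out/|beta_exp|."""
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta: Wald ratio undefined")
    return by / bx, sy / np.abs(bx)


def mr_ivw(data: pd.DataFrame, outcome: str = "outcome", random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2); fixed-effect SE
    sqrt(1/sum(bx^2/sy^2)). ``random_effects`` applies the multiplicative
    overdispersion factor (residual sd of the weighted through-origin
    regression, floored at 1).
    """
    if len(data) < 2:
        raise ValueError("IVW needs at least 2 variants")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = float(np.sqrt(1.0 / denom))
    if random_effects and len(data) > 2:
        resid = (by - beta * bx) * np.sqrt(w)
        phi = float(resid @ resid) / (len(data) - 1)
        se *= max(1.0, np.sqrt(phi))
    return MRResult(outcome=outcome, estimator="ivw", beta=beta, se=se,
                    p=_normal_p(beta / se), n_variants=len(data))


def mr_egger(data: pd.DataFrame, outcome: str = "outcome") -> MRResult:
    """Egger regression: WLS of by on bx with a free intercept, weights
    1/sy^2, after jointly flipping (bx, by) pairs so every bx >= 0. The
    slope is the causal estimate; a nonzero intercept indicates directional
    pleiotropy."""
    if len(data) < 3:
        raise ValueError("Egger regression needs at least 3 variants")
    bx = data["beta_exp"].to_numpy(dtype=float).copy()
    by = data["beta_out"].to_numpy(dtype=float).copy()
    sy = data["se_out"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    X = np.column_stack([np.ones_like(bx), bx])
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    slope, slope_se = float(res.params[1]), float(res.bse[1])
    icpt, icpt_se = float(res.params[0]), float(res.bse[0])
    df = len(data) - 2
    slope_p = max(2.0 * stats.t.sf(abs(slope / slope_se), df), np.finfo(float).tiny)
    icpt_p = max(2.0 * stats.t.sf(abs(icpt / icpt_se), df), np.finfo(float).tiny)
    return MRResult(outcome=outcome, estimator="egger", beta=slope, se=slope_se, p=slope_p,
                    n_variants=len(data), egger_intercept=icpt, egger_intercept_p=icpt_p)


def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation.

    Order the ratios; with normalized weights w_(j), the cumulative
    midpoint weight is s_j = sum_{k<=j} w_(k) - w_(j)/2; the estimate
    interpolates linearly between the ratios bracketing s = 0.5.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def mr_weighted_median(
    data: pd.DataFrame, n_boot: int = 1000, seed: int = 0, outcome: str = "outcome"
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratios are weighted by their inverse delta-method variances. The SE is
    the standard deviation of estimates recomputed on ``n_boot`` parametric
    resamples of (beta_exp, beta_out) at their stated SEs; the bootstrap
    stream is fully determined by ``seed``.
    """
    if len(data) < 3:
        raise ValueError("weighted median needs at least 3 variants")
    ratios, ratio_se = wald_ratios(data)
    weights = 1.0 / ratio_se**2
    beta = weighted_median_estimate(ratios, weights)

    rng = substream(seed, "wm_boot")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sx = data["se_exp"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0.0, sx)
        byb = by + rng.normal(0.0, sy)
        bxb = np.where(bxb == 0, 1e-12, bxb)
        rb = byb / bxb
        wb = bxb**2 / sy**2
        boots[b] = weighted_median_estimate(rb, wb)
    se = float(boots.std(ddof=1))
    p = _normal_p(beta / se) if se > 0 else np.nan
    return MRResult(outcome=outcome, estimator="weighted_median", beta=beta, se=se, p=p,
                    n_variants=len(data))
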