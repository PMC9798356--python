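"""Phenome-wide observational association and disease-burden analysis.

Each retained phecode (>= 200 cases and >= 200 controls) is tested by
logistic regression of case status on the exposure (standardized BMI or a
genetic score), adjusted for age, sex and ten principal components, with
Wald statistics; significance is gated by Bonferroni over the number of
codes tested. The burden analysis counts, per individual, how many of the
exposure-associated codes they carry, summarizes the count by BMI category
(<25, 25-30, 30-40, >=40, lower bounds inclusive) and tests for trend.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import PhecodeTable

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_bmi",
    "filter_phecodes",
    "run_phewas",
    "bonferroni_threshold",
    "disease_burden",
    "phewas_design",
]

PHEWAS_COVARIATES = ("age", "sex") + tuple(f"pc{k}" for k in range(1, 11))


def standardize_bmi(trait: pd.DataFrame) -> np.ndarray:
    """(bmi - mean(bmi)) / sd(bmi), sample SD with denominator n-1."""
    x = trait["bmi"].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("BMI is constant: cannot standardize")
    return (x - x.mean()) / sd


def filter_phecodes(
    phecodes: PhecodeTable, min_cases: int = 200, min_controls: int = 200
) -> PhecodeTable:
    """Drop phecodes with fewer than ``min_cases`` cases or ``min_controls``
    controls (boundary counts are retained)."""
    counts = phecodes.counts()
    keep = counts.loc[
        (counts["n_cases"] >= min_cases) & (counts["n_controls"] >= min_controls), "code"
    ].tolist()
    dropped = len(phecodes.codes) - len(keep)
    if dropped:
        logger.info("filter_phecodes: removed %d of %d codes", dropped, len(phecodes.codes))
    meta = phecodes.meta.loc[phecodes.meta["code"].isin(keep)].reset_index(drop=True)
    return PhecodeTable(status=phecodes.status[keep].copy(), meta=meta)


def phewas_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex(male=1) + pc1..pc10 design block."""
    n = len(covariates)
    cols = [np.ones(n), covariates["age"].to_numpy(dtype=float),
            (covariates["sex"] == "male").to_numpy(dtype=float)]
    cols += [covariates[f"pc{k}"].to_numpy(dtype=float) for k in range(1, 11)]
    return np.column_stack(cols)


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """Maximum-likelihood logistic fit; returns (beta, se, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton", tol=1e-8)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError, ValueError):
            return None
    conv = bool(res.mle_retvals.get("converged", True))
    if not np.all(np.isfinite(res.bse)):
        return None
    return res.params, res.bse, conv


def run_phewas(
    exposure: np.ndarray,
    phecodes: PhecodeTable,
    covariates: pd.DataFrame,
    exposure_name: str = "bmi_std",
) -> pd.DataFrame:
    """Per-phecode logistic regression of status on exposure + age + sex +
    pc1..pc10.

    Returns one row per code: n_cases, n_controls, beta (log-OR per unit of
    exposure), se, p, or, ci_low, ci_high, flagged (non-convergence or
    separation; flagged rows carry NaN statistics and are excluded from
    significance counts downstream).
    """
    exposure = np.asarray(exposure, dtype=float)
    if exposure.std(ddof=0) == 0:
        raise ValueError("constant exposure")
    Xc = phewas_design(covariates)
    X = np.column_stack([Xc[:, :1], exposure, Xc[:, 1:]])  # exposure is column 1
    rows = []
    for code in phecodes.codes:
        y = phecodes.status[code].to_numpy(dtype=float)
        n_cases = int(y.sum())
        n_controls = int(len(y) - n_cases)
        fit = _fit_logistic(y, X)
        if fit is None or not fit[2]:
            logger.info("run_phewas: flagged %s (separation or non-convergence)", code)
            rows.append(
                {"phecode": code, "exposure": exposure_name, "n_cases": n_cases,
                 "n_controls": n_controls, "beta": np.nan, "se": np.nan, "p": np.nan,
                 "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "flagged": True}
            )
            continue
        params, bse, _ = fit
        b, s = float(params[1]), float(bse[1])
        z = b / s
        p = max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)
        rows.append(
            {"phecode": code, "exposure": exposure_name, "n_cases": n_cases,
             "n_controls": n_controls, "beta": b, "se": s, "p": p,
             "or": float(np.exp(b)), "ci_low": float(np.exp(b - 1.96 * s)),
             "ci_high": float(np.exp(b + 1.96 * s)), "flagged": False}
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def disease_burden(
    phecodes: PhecodeTable,
    associated_codes: list[str],
    trait: pd.DataFrame,
    cut_points: tuple[float, ...] = (25.0, 30.0, 40.0),
) -> tuple[pd.DataFrame, float]:
    """Per-BMI-category burden of associated disease codes.

    Each individual's burden is their number of case statuses among
    ``associated_codes``. Categories are left-closed intervals from the cut
    points (BMI exactly at a cut point falls in the upper category). The
    trend p-value is from OLS of burden on the ordinal category index over
    individuals in non-empty categories; with no variation in burden the
    trend is reported as p = 1.
    """
    codes = [c for c in associated_codes if c in phecodes.status.columns]
    burden = phecodes.status[codes].sum(axis=1).to_numpy(dtype=float) if codes else np.zeros(len(trait))
    bmi = trait["bmi"].to_numpy(dtype=float)
    cat_idx = np.digitize(bmi, cut_points)  # right-open bins: cut point joins upper bin

    edges = [-np.inf, *cut_points, np.inf]
    labels = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        if np.isinf(lo):
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"[{lo:g},{hi:g})")

    rows = []
    for k, lab in enumerate(labels):
        mask = cat_idx == k
        rows.append(
            {"category": lab, "n": int(mask.sum()),
             "mean_burden": float(burden[mask].mean()) if mask.any() else np.nan,
             "median_burden": float(np.median(burden[mask])) if mask.any() else np.nan}
        )
    summary = pd.DataFrame(rows)

    nonempty = np.isin(cat_idx, [k for k in range(len(labels)) if (cat_idx == k).any()])
    x = cat_idx[nonempty].astype(float)
    y = burden[nonempty]
    if y.std(ddof=0) == 0 or x.std(ddof=0) == 0:
        trend_p = 1.0
    else:
        res = stats.linregress(x, y)
        trend_p = float(res.pvalue)
    return summary, trend_p
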