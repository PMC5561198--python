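"""Cohort-level statistics: acceptance summaries, age regressions, and
mediation with bias-corrected bootstrap confidence intervals.

The mediation model asks how much of the age → reciprocity-index relation
is transmitted through regional cortical thickness.  Three OLS equations
share the covariates (sex, IQ):

    thickness ~ age + covariates                 (path a: age → thickness)
    index ~ age + thickness + covariates         (path b, direct effect c')
    index ~ age + covariates                     (total effect c)

The indirect effect is a*b, and for linear models with identical covariates
the decomposition c = c' + a*b holds exactly.  Significance of the indirect
(and direct) effect is judged by a bias-corrected (BC) percentile bootstrap
over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .games import CONDITIONS

__all__ = [
    "AgeRegressionResult",
    "MediationResult",
    "acceptance_by_condition",
    "regress_index_on_age",
    "mediate",
]

DEFAULT_COVARIATES = ("sex", "iq")


def acceptance_by_condition(trials: pd.DataFrame, unfair_only: bool = True) -> pd.DataFrame:
    """Per-subject, per-condition acceptance rates.

    By default only unfair chosen divisions (responder payoff strictly below
    half the stake) enter, matching the behavioral summary of interest.
    Subjects with no qualifying trials in a condition get NaN there.
    """
    required = {"subject_id", "condition", "action", "x_i", "x_j"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table is missing columns {sorted(missing)}")
    df = trials
    if unfair_only:
        df = df[df["x_j"] < (df["x_i"] + df["x_j"]) / 2.0]
    from .models import encode_actions

    df = df.assign(_acc=encode_actions(df["action"]))
    rates = (df.groupby(["subject_id", "condition"], sort=False)["_acc"]
               .mean().unstack("condition"))
    return rates.reindex(columns=[c for c in CONDITIONS if c in rates.columns])


@dataclass(frozen=True)
class AgeRegressionResult:
    """OLS slope of the reciprocity index on age, controlling sex and IQ."""

    slope: float
    se: float
    t: float
    p: float
    n: int
    params: pd.Series


def regress_index_on_age(cohort: pd.DataFrame,
                         outcome: str = "reciprocity_index",
                         covariates=DEFAULT_COVARIATES) -> AgeRegressionResult:
    """Multiple regression predicting the reciprocity index by age,
    controlling for sex and IQ; two-sided p for the age coefficient."""
    cols = ["age", *covariates, outcome]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    df = cohort[cols].dropna()
    if len(df) < len(cols) + 1:
        raise ValueError(f"need at least {len(cols) + 1} complete subjects")
    X = sm.add_constant(df[["age", *covariates]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(df[outcome].astype(float), X).fit()
    return AgeRegressionResult(
        slope=float(res.params["age"]),
        se=float(res.bse["age"]),
        t=float(res.tvalues["age"]),
        p=float(res.pvalues["age"]),
        n=int(res.nobs),
        params=res.params,
    )


@dataclass(frozen=True)
class MediationResult:
    """Mediation of the age → index relation through one ROI's thickness."""

    roi: str
    path_a: float
    path_b: float
    direct: float
    total: float
    indirect: float
    ratio_indirect_total: float
    indirect_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    n_boot: int
    n: int


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _paths(age, med, out, cov):
    """(a, b, direct, total) from the three shared-covariate OLS fits."""
    n = len(age)
    ones = np.ones(n)
    Xa = np.column_stack([ones, age, cov])
    a = _ols_beta(Xa, med)[1]
    Xb = np.column_stack([ones, age, med, cov])
    bet = _ols_beta(Xb, out)
    direct, b = bet[1], bet[2]
    total = _ols_beta(Xa, out)[1]
    return a, b, direct, total


def _bc_ci(boot: np.ndarray, point: float, alpha: float = 0.05):
    """Bias-corrected percentile bootstrap interval.

    The correction shifts the percentile cut points by twice the normal
    quantile of the fraction of bootstrap replicates below the point
    estimate (median-bias correction).
    """
    boot = boot[np.isfinite(boot)]
    prop = np.clip(np.mean(boot < point), 1.0 / (len(boot) + 1),
                   1.0 - 1.0 / (len(boot) + 1))
    z0 = norm.ppf(prop)
    lo = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    hi = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    return (float(np.quantile(boot, lo)), float(np.quantile(boot, hi)))


def mediate(cohort: pd.DataFrame, roi: str, n_boot: int = 10_000, seed=None,
            outcome: str = "reciprocity_index",
            covariates=DEFAULT_COVARIATES) -> MediationResult:
    """Thickness-mediated indirect effect of age on the reciprocity index.

    Bias-corrected percentile bootstrap (over subjects, seeded) for the
    indirect effect a*b and the direct effect c'.  The ratio of indirect to
    total effect is reported as NaN when the total effect is numerically
    zero.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for stable BC intervals")
    cols = ["age", roi, outcome, *covariates]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    df = cohort[cols].dropna()
    n = len(df)
    if n < len(cols) + 2:
        raise ValueError("too few complete cases for the mediation model")
    age = df["age"].to_numpy(float)
    med = df[roi].to_numpy(float)
    out = df[outcome].to_numpy(float)
    cov = df[list(covariates)].to_numpy(float)
    if np.ptp(med) == 0:
        raise ValueError(f"zero-variance mediator {roi!r}")

    a, b, direct, total = _paths(age, med, out, cov)
    indirect = a * b
    ratio = float("nan") if abs(total) < 1e-12 else indirect / total

    rng = np.random.default_rng(seed)
    boot_ind = np.empty(n_boot)
    boot_dir = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        m = med[idx]
        if np.ptp(m) == 0:
            boot_ind[i] = boot_dir[i] = np.nan
            continue
        ab, bb, db, _ = _paths(age[idx], m, out[idx], cov[idx])
        boot_ind[i] = ab * bb
        boot_dir[i] = db

    return MediationResult(
        roi=roi,
        path_a=float(a),
        path_b=float(b),
        direct=float(direct),
        total=float(total),
        indirect=float(indirect),
        ratio_indirect_total=float(ratio),
        indirect_ci=_bc_ci(boot_ind, indirect),
        direct_ci=_bc_ci(boot_dir, direct),
        n_boot=n_boot,
        n=n,
    )
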