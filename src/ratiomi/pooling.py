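"""Rubin's rules for combining per-imputation fits, with MI diagnostics.

For a scalar parameter estimated as Q_hat_j with squared standard error
U_j on imputation j = 1..M:

* pooled estimate  Q_bar = mean(Q_hat_j)
* within variance  W = mean(U_j)
* between variance B = sample variance of Q_hat_j
* total variance   T = W + (1 + 1/M) B
* lambda = (1 + 1/M) B / T, reported as the fraction of missing
  information (FMI); the nu-adjusted FMI variant differs only at small M
  and is not used here
* degrees of freedom by the Barnard-Rubin small-sample formula using the
  complete-data residual df (treated as infinite for Cox fits)
* 95% CI = Q_bar +/- t_{nu, 0.975} sqrt(T)
* relative efficiency versus infinitely many imputations = 1/(1 + FMI/M)
* Monte Carlo error of the point estimate = sqrt(B/M)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fits import FitResult, fit_cox, fit_linear
from .mvn import ImputationStack

__all__ = ["PooledResult", "rubin_pool", "pool_stack"]


@dataclass(frozen=True)
class PooledResult:
    coefficient: str
    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    fmi: float
    relative_efficiency: float
    mc_error: float
    m: int

    @property
    def std_error(self) -> float:
        return float(np.sqrt(self.total))


def _barnard_rubin_df(m: int, lam: float, df_complete: float) -> float:
    if lam <= 0:
        lam = 0.0
    if np.isinf(df_complete):
        nu_obs = np.inf
    else:
        nu_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
    if lam == 0:
        return float(nu_obs)
    nu_old = (m - 1) / lam**2
    if np.isinf(nu_obs):
        return float(nu_old)
    return float(1.0 / (1.0 / nu_old + 1.0 / nu_obs))


def rubin_pool(
    fits: Sequence[FitResult],
    coefficient: str,
    df_complete: float | None = None,
) -> PooledResult:
    """Pool one coefficient across M >= 2 per-imputation fits."""
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin's rules need M >= 2 (between-variance undefined)")
    for f in fits:
        if coefficient not in f.estimates.index:
            raise KeyError(
                f"coefficient {coefficient!r} absent from fit "
                f"(has {list(f.estimates.index)})"
            )
    est = np.array([f.estimates[coefficient] for f in fits], dtype=float)
    ses = np.array([f.std_errors[coefficient] for f in fits], dtype=float)
    if df_complete is None:
        df_complete = fits[0].df_complete
    q_bar = est.mean()
    w = float(np.mean(ses**2))
    b = float(np.var(est, ddof=1))
    t_var = w + (1 + 1 / m) * b
    lam = (1 + 1 / m) * b / t_var if t_var > 0 else 0.0
    nu = _barnard_rubin_df(m, lam, df_complete)
    tq = stats.t.ppf(0.975, nu) if np.isfinite(nu) else stats.norm.ppf(0.975)
    half = tq * np.sqrt(t_var)
    return PooledResult(
        coefficient=coefficient,
        estimate=float(q_bar),
        within=w,
        between=b,
        total=float(t_var),
        df=float(nu),
        ci_low=float(q_bar - half),
        ci_high=float(q_bar + half),
        fmi=float(lam),
        relative_efficiency=float(1.0 / (1.0 + lam / m)),
        mc_error=float(np.sqrt(b / m)),
        m=m,
    )


def _analysis_fit(df: pd.DataFrame, roles) -> FitResult:
    covs = [roles.ratio, *roles.incomplete_covariates, *roles.complete_covariates]
    X = df[covs]
    if roles.family == "continuous":
        return fit_linear(X, df[roles.outcome])
    return fit_cox(X, df[roles.time], df[roles.event])


def pool_stack(stack: ImputationStack) -> pd.DataFrame:
    """Fit the analysis model on every imputation and pool each coefficient.

    The analysis model regresses the outcome on the ratio plus the other
    covariates (linear regression for a continuous outcome, Cox for a
    survival outcome). Returns a tidy table with one row per coefficient.
    """
    fits = [_analysis_fit(df, stack.roles) for df in stack.datasets]
    rows = []
    for coef in fits[0].estimates.index:
        p = rubin_pool(fits, coef)
        rows.append(
            {
                "coefficient": p.coefficient,
                "estimate": p.estimate,
                "se": p.std_error,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "df": p.df,
                "within": p.within,
                "between": p.between,
                "fmi": p.fmi,
                "relative_efficiency": p.relative_efficiency,
                "mc_error": p.mc_error,
            }
        )
    return pd.DataFrame(rows).set_index("coefficient")
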