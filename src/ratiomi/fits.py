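"""Analysis-model fits on completed datasets.

Continuous outcomes use ordinary least squares (classical standard errors,
via statsmodels). Survival outcomes use the Cox proportional-hazards model
fitted by Newton-Raphson on the Breslow partial likelihood, with standard
errors from the inverse observed information; the baseline hazard is
profiled out and not returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConvergenceError

__all__ = ["FitResult", "fit_linear", "fit_cox", "cox_partial_loglik"]


@dataclass(frozen=True)
class FitResult:
    """Point estimates and classical standard errors from one fitted model."""

    estimates: pd.Series
    std_errors: pd.Series
    df_complete: float  # residual df for OLS; inf for Cox
    n_used: int


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the (near-)collinear columns if X is rank deficient."""
    if X.shape[0] < X.shape[1]:
        raise np.linalg.LinAlgError("more columns than rows")
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    R = np.linalg.qr(X / scale, mode="r")
    small = np.abs(np.diag(R)) < 1e-8
    if small.any():
        bad = [names[j] for j in np.flatnonzero(small)]
        raise ConvergenceError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def fit_linear(X: pd.DataFrame, y) -> FitResult:
    """OLS of y on X plus an intercept, with classical standard errors."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    design = sm.add_constant(X, has_constant="add")
    _check_full_rank(design.to_numpy(dtype=float), list(design.columns))
    res = sm.OLS(y, design).fit()
    return FitResult(
        estimates=pd.Series(res.params, index=design.columns),
        std_errors=pd.Series(res.bse, index=design.columns),
        df_complete=float(res.df_resid),
        n_used=n,
    )


def _breslow_quantities(Xs, ts, es, beta, event_idx, risk_start):
    """Log partial likelihood, score and information under Breslow ties.

    Rows must be sorted by ascending time; ``risk_start[i]`` is the first
    sorted index belonging to the risk set of event row i (everyone with
    time >= t_i, censored-at-event-time subjects included).
    """
    n, p = Xs.shape
    eta = Xs @ beta
    eta_c = eta - eta.max()
    w = np.exp(eta_c)
    # suffix sums over the ascending sort: S0[i] = sum_{j >= i} w_j etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1],
                   axis=0)[::-1]
    idx = risk_start[event_idx]
    s0 = S0[idx]
    xbar = S1[idx] / s0[:, None]
    # the max-subtraction cancels between eta_c and log S0
    ll = float(np.sum(eta_c[event_idx] - np.log(s0)))
    score = (Xs[event_idx] - xbar).sum(axis=0)
    info = (S2[idx] / s0[:, None, None]).sum(axis=0) - np.einsum(
        "ip,iq->pq", xbar, xbar
    )
    return ll, score, info


def cox_partial_loglik(X, times, events, beta):
    """Breslow log partial likelihood and score at ``beta`` (diagnostics/tests)."""
    Xs, ts, es, event_idx, risk_start, names = _prepare_cox(X, times, events)
    ll, score, _ = _breslow_quantities(Xs, ts, es, np.asarray(beta, float),
                                       event_idx, risk_start)
    return ll, score


def _prepare_cox(X, times, events):
    X = pd.DataFrame(X)
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (events == 1).any():
        raise ValueError("Cox fit requires at least one event")
    order = np.argsort(times, kind="stable")
    Xs, ts, es = Xa[order], times[order], events[order].astype(int)
    event_idx = np.flatnonzero(es == 1)
    # first sorted index with time >= t_i: ties share the full risk set
    risk_start = np.searchsorted(ts, ts, side="left")
    return Xs, ts, es, event_idx, risk_start, names


def fit_cox(X, times, events, max_iter: int = 100, tol: float = 1e-9) -> FitResult:
    """Cox proportional hazards by Newton-Raphson on the Breslow partial likelihood.

    Convergence: relative change in log partial likelihood < ``tol``.
    Standard errors come from the inverse observed information. Monotone
    likelihood (perfect separation in the risk ordering) raises an error.
    """
    Xs, ts, es, event_idx, risk_start, names = _prepare_cox(X, times, events)
    Xmean = Xs.mean(axis=0)
    Xc = Xs - Xmean  # centred for numerical stability; beta unchanged
    _check_full_rank(Xc[risk_start < len(ts)], names)
    n, p = Xc.shape
    beta = np.zeros(p)
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, score, info = _breslow_quantities(Xc, ts, es, beta, event_idx, risk_start)
        if not np.isfinite(ll):
            raise ConvergenceError(
                "log partial likelihood diverged; check for separation"
            )
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix (collinear covariates?): {exc}"
            ) from exc
        beta = beta + step
        if np.abs(beta).max() > 50:
            raise ConvergenceError(
                "coefficients diverging: likely monotone likelihood / perfect "
                "separation in the risk ordering; remove or recode the covariate"
            )
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(abs(ll_prev), 1.0):
            break
        ll_prev = ll
    else:
        raise ConvergenceError(f"Cox Newton-Raphson failed in {max_iter} iterations")
    _, _, info = _breslow_quantities(Xc, ts, es, beta, event_idx, risk_start)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        estimates=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        df_complete=float("inf"),
        n_used=n,
    )
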