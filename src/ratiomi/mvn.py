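"""Joint multivariate-normal imputation by Bayesian data augmentation.

The imputation model is a multivariate-normal regression of the modelled
incomplete variables V on a complete regressor vector u (intercept, the
encoded outcome f(y), and the complete covariates w):

    V_i | u_i  ~  MVN(Theta' u_i, Sigma).

Missing cells are drawn by alternating an I-step (each row's missing V
coordinates are drawn from their exact Gaussian conditional given the row's
observed V coordinates and u) with a P-step (Sigma from its inverse-Wishart
full conditional and Theta from its matrix-normal full conditional, under
the Jeffreys-type noninformative prior p(Theta, Sigma) ∝ |Sigma|^-(p+1)/2).
The chain starts from the EM maximiser of the observed-data likelihood,
runs a burn-in, then stores one completed dataset every `thin` iterations
until M have been collected.

Numerical safeguards: a 1e-10 diagonal jitter is applied before any
Cholesky factorisation that fails, leaving draws materially unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .datamodel import ColumnRoles, IncompleteDataset
from .errors import ConvergenceError, DomainError, ImputationError
from .outcomes import encode_outcome

__all__ = [
    "MVNState",
    "EngineSettings",
    "ImputationStack",
    "conditional_normal",
    "em_start",
    "da_iterate",
    "impute_mvn",
]

_JITTER = 1e-10


@dataclass
class MVNState:
    """Parameters of the conditional MVN imputation model.

    ``coefficients`` is the |u| x |V| matrix Theta mapping the regressor
    vector to the mean of the modelled variables; ``residual_covariance`` is
    the symmetric positive-definite residual covariance Sigma over V.
    """

    coefficients: np.ndarray
    residual_covariance: np.ndarray
    regressors: tuple[str, ...] = ()
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        Theta = np.asarray(self.coefficients, dtype=float)
        Sigma = np.asarray(self.residual_covariance, dtype=float)
        if Theta.ndim != 2 or Sigma.shape != (Theta.shape[1], Theta.shape[1]):
            raise ValueError("coefficients must be |u| x |V| and covariance |V| x |V|")
        if not np.allclose(Sigma, Sigma.T):
            raise ValueError("residual covariance must be symmetric")
        if np.linalg.eigvalsh(Sigma).min() <= 0:
            raise ValueError("residual covariance must be positive definite")
        self.coefficients = Theta
        self.residual_covariance = Sigma


@dataclass(frozen=True)
class EngineSettings:
    """MCMC settings for the imputation engine.

    Defaults follow standard practice for this engine family: burn-in of
    1000 iterations, one stored dataset every 10th iteration thereafter,
    M = 5 imputations. Ten iterations between stored datasets may
    under-separate imputations when the missing fraction is large; raise
    ``thin`` if autocorrelation diagnostics suggest it.
    """

    m: int = 5
    burn_in: int = 1000
    thin: int = 10
    seed: int | np.random.SeedSequence | None = None
    prior: str = "jeffreys"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m >= 2 is required (Rubin's rules need between-variance)")
        if self.burn_in < 1 or self.thin < 1:
            raise ValueError("burn_in and thin must be >= 1")
        if self.prior != "jeffreys":
            raise ValueError(f"unknown P-step prior {self.prior!r}")


@dataclass
class ImputationStack:
    """M completed copies of a dataset plus provenance.

    ``mask`` is the original observed mask: it is what distinguishes imputed
    cells from observed ones downstream (passive derivation, diagnostics).
    """

    datasets: list[pd.DataFrame]
    strategy: str
    settings: object
    roles: ColumnRoles
    mask: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.datasets)


def _chol_lower(a: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, retrying once with a 1e-10 diagonal jitter."""
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        pass
    try:
        return np.linalg.cholesky(a + _JITTER * np.eye(a.shape[0]))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise ImputationError(f"covariance not positive definite: {exc}") from exc


def conditional_normal(mean, cov, observed_index, observed_values):
    """Exact Gaussian conditional of the unobserved coordinates.

    Given a joint N(mean, cov) over p coordinates, condition on the subset
    ``observed_index`` taking ``observed_values``; returns the conditional
    mean and covariance of the remaining coordinates (Schur complement).
    An empty observed set returns (mean, cov) unchanged.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    p = mean.size
    obs = np.asarray(observed_index, dtype=int)
    if obs.size == 0:
        return mean.copy(), cov.copy()
    if obs.size >= p:
        raise ValueError("observed_index must be a strict subset of coordinates")
    vals = np.asarray(observed_values, dtype=float)
    mis = np.setdiff1d(np.arange(p), obs)
    Soo = cov[np.ix_(obs, obs)]
    try:
        L = _chol_lower(Soo)
    except ImputationError as exc:
        raise ImputationError(
            f"singular covariance among observed coordinates {obs.tolist()}: {exc}"
        ) from exc
    A = cho_solve((L, True), cov[np.ix_(obs, mis)])
    cond_mean = mean[mis] + (vals - mean[obs]) @ A
    cond_cov = cov[np.ix_(mis, mis)] - cov[np.ix_(mis, obs)] @ A
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    return cond_mean, cond_cov


_BARTLETT_CACHE: dict[int, tuple] = {}


def _bartlett_indices(p: int) -> tuple:
    if p not in _BARTLETT_CACHE:
        _BARTLETT_CACHE[p] = (np.diag_indices(p), np.tril_indices(p, -1))
    return _BARTLETT_CACHE[p]


def _invwishart_rvs(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from the inverse-Wishart with scale matrix S (mean S/(df-p-1)).

    Bartlett construction: W ~ Wishart(df, S^-1) via W = (C A)(C A)' with
    C C' = S^-1 and A the lower-triangular Bartlett factor; returns W^-1,
    computed as (L A^-T)(L A^-T)' with L the Cholesky factor of S.
    """
    p = scale.shape[0]
    if df <= p - 1:
        raise ImputationError(f"inverse-Wishart degrees of freedom {df} <= {p - 1}")
    L = _chol_lower(scale)
    A = np.zeros((p, p))
    diag_idx, tril_idx = _bartlett_indices(p)
    A[diag_idx] = np.sqrt(rng.chisquare(df - np.arange(p)))
    if p > 1:
        A[tril_idx] = rng.standard_normal(p * (p - 1) // 2)
    M = L @ np.linalg.inv(A).T
    return M @ M.T


class _Augmenter:
    """Precomputed workspace for EM and data augmentation on one dataset.

    Holds the modelled-variable matrix V (NaN for missing), the complete
    regressor matrix U, the distinct missingness patterns grouped over rows
    and the fixed factorisations of U'U, so that each chain iteration is a
    handful of small dense operations.
    """

    def __init__(self, V: np.ndarray, U: np.ndarray,
                 variables: Sequence[str], regressors: Sequence[str]):
        self.V = np.asarray(V, dtype=float)
        self.U = np.asarray(U, dtype=float)
        self.variables = tuple(variables)
        self.regressors = tuple(regressors)
        self.n, self.p = self.V.shape
        self.q = self.U.shape[1]
        if np.isnan(self.U).any():
            raise DomainError("regressors u must be fully observed")
        if self.n <= self.q + self.p:
            raise ImputationError(
                f"P-step degenerate: n={self.n} <= |u|+|V|={self.q + self.p}"
            )
        self.obs = ~np.isnan(self.V)
        fully_missing = [
            self.variables[j] for j in range(self.p) if not self.obs[:, j].any()
        ]
        if fully_missing:
            raise DomainError(
                f"modelled variables with no observed values: {fully_missing}; "
                "drop them from the imputation model"
            )
        self.V0 = np.where(self.obs, self.V, 0.0)
        self.any_missing = bool((~self.obs).any())

        patterns, inverse = np.unique(self.obs, axis=0, return_inverse=True)
        self.groups = []
        for g in range(patterns.shape[0]):
            o = patterns[g]
            if o.all():
                continue
            rows = np.flatnonzero(inverse == g)
            m = ~o
            o_idx = np.flatnonzero(o)
            m_idx = np.flatnonzero(m)
            self.groups.append(
                (rows, o_idx, m_idx, np.ix_(o_idx, o_idx), np.ix_(o_idx, m_idx),
                 np.ix_(m_idx, m_idx), np.ix_(m_idx, o_idx),
                 rows[:, None], m_idx[None, :])
            )

        self.UtU = self.U.T @ self.U
        self._Lu = _chol_lower(self.UtU)
        # A_mn A_mn' = (U'U)^-1, used for the matrix-normal Theta draw
        inv_Lu = solve_triangular(self._Lu, np.eye(self.q), lower=True)
        self._A_mn = inv_Lu.T
        self._UtU_inv = inv_Lu.T @ inv_Lu
        self.df_sigma = self.n - self.q

    # ---- likelihood machinery -------------------------------------------

    def _theta_hat(self, Vc: np.ndarray) -> np.ndarray:
        return self._UtU_inv @ (self.U.T @ Vc)

    def istep(self, theta: np.ndarray, sigma: np.ndarray,
              rng: np.random.Generator, rows_filter=None) -> np.ndarray:
        """Draw all missing V cells from their conditionals; returns completed V."""
        Vc = self.V0.copy()
        mu = self.U @ theta
        for (rows, o_idx, m_idx, oo, om, mm, mo, rows_c, m_r) in self.groups:
            if rows_filter is not None:
                rows_mask = np.isin(rows, rows_filter)
                if not rows_mask.any():
                    continue
                rows = rows[rows_mask]
                rows_c = rows[:, None]
            if o_idx.size:
                A = np.linalg.solve(sigma[oo], sigma[om])
                cond_cov = sigma[mm] - sigma[mo] @ A
                cond_mean = mu[rows][:, m_idx] + (
                    self.V0[rows][:, o_idx] - mu[rows][:, o_idx]
                ) @ A
            else:
                cond_cov = sigma[mm]
                cond_mean = mu[rows][:, m_idx]
            Lc = _chol_lower(0.5 * (cond_cov + cond_cov.T))
            Vc[rows_c, m_r] = cond_mean + rng.standard_normal(
                (rows.size, m_idx.size)
            ) @ Lc.T
        return Vc

    def pstep(self, Vc: np.ndarray, rng: np.random.Generator):
        """Draw (Theta, Sigma) from their full conditionals given completed data."""
        theta_hat = self._theta_hat(Vc)
        S = Vc.T @ Vc - theta_hat.T @ self.UtU @ theta_hat
        S = 0.5 * (S + S.T)
        sigma = _invwishart_rvs(rng, self.df_sigma, S)
        theta = theta_hat + self._A_mn @ rng.standard_normal(
            (self.q, self.p)
        ) @ _chol_lower(sigma).T
        return theta, sigma

    def em(self, tol: float = 1e-8, max_iter: int = 500):
        """EM estimate of (Theta, Sigma) maximising the observed-data likelihood."""
        # start from mean-filled data
        col_means = np.nanmean(self.V, axis=0)
        Vf = np.where(self.obs, self.V0, col_means)
        theta = self._theta_hat(Vf)
        resid = Vf - self.U @ theta
        sigma = resid.T @ resid / self.n
        sigma = 0.5 * (sigma + sigma.T) + _JITTER * np.eye(self.p)
        ll_prev = -np.inf
        for _ in range(max_iter):
            mu = self.U @ theta
            EV = np.where(self.obs, self.V0, 0.0)
            Csum = np.zeros((self.p, self.p))
            ll = 0.0
            for (rows, o_idx, m_idx, oo, om, mm, mo, rows_c, m_r) in self.groups:
                if o_idx.size:
                    L = _chol_lower(sigma[oo])
                    A = cho_solve((L, True), sigma[om])
                    cond_cov = sigma[mm] - sigma[mo] @ A
                    resid_o = self.V0[rows][:, o_idx] - mu[rows][:, o_idx]
                    EV[rows_c, m_r] = mu[rows][:, m_idx] + resid_o @ A
                    # observed-data log-likelihood contribution of this pattern
                    z = solve_triangular(L, resid_o.T, lower=True)
                    ll += (
                        -0.5 * rows.size * (o_idx.size * np.log(2 * np.pi))
                        - rows.size * np.log(np.diag(L)).sum()
                        - 0.5 * (z ** 2).sum()
                    )
                else:
                    EV[rows_c, m_r] = mu[rows][:, m_idx]
                    cond_cov = sigma[mm]
                Csum[mm] += rows.size * cond_cov
            # complete rows' likelihood
            full_rows = self.obs.all(axis=1)
            if full_rows.any():
                L_full = _chol_lower(sigma)
                resid_f = (self.V0[full_rows] - mu[full_rows]).T
                z = solve_triangular(L_full, resid_f, lower=True)
                nf = int(full_rows.sum())
                ll += (
                    -0.5 * nf * self.p * np.log(2 * np.pi)
                    - nf * np.log(np.diag(L_full)).sum()
                    - 0.5 * (z ** 2).sum()
                )
            S_uv = self.U.T @ EV
            S_vv = EV.T @ EV + Csum
            theta = cho_solve((self._Lu, True), S_uv)
            sigma = (S_vv - theta.T @ self.UtU @ theta) / self.n
            sigma = 0.5 * (sigma + sigma.T)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
                break
            ll_prev = ll
        return theta, sigma, ll


def _regressor_matrix(ds: IncompleteDataset) -> tuple[np.ndarray, tuple[str, ...]]:
    """Complete regressor matrix u: intercept, encoded outcome f(y), then w."""
    enc = encode_outcome(ds)
    parts = [np.ones((ds.n, 1)), enc.columns.to_numpy(dtype=float)]
    names = ["const", *enc.columns.columns]
    w = list(ds.roles.complete_covariates)
    if w:
        parts.append(ds.data[w].to_numpy(dtype=float))
        names += w
    return np.hstack(parts), tuple(names)


def _make_augmenter(ds: IncompleteDataset, model_vars: Sequence[str]) -> _Augmenter:
    missing_cols = [v for v in model_vars if v not in ds.data.columns]
    if missing_cols:
        raise DomainError(f"modelled variables absent from dataset: {missing_cols}")
    U, names = _regressor_matrix(ds)
    V = ds.data[list(model_vars)].to_numpy(dtype=float)
    return _Augmenter(V, U, model_vars, names)


def em_start(ds: IncompleteDataset, model_vars: Sequence[str]) -> MVNState:
    """EM starting values (Theta, Sigma) for the data-augmentation chain."""
    aug = _make_augmenter(ds, model_vars)
    theta, sigma, _ = aug.em()
    return MVNState(theta, sigma + _JITTER * np.eye(aug.p),
                    aug.regressors, aug.variables)


def da_iterate(
    state: MVNState, ds: IncompleteDataset, rng: np.random.Generator
) -> tuple[MVNState, pd.DataFrame]:
    """One data-augmentation iteration: I-step then P-step.

    Returns the new parameter draw and a completed copy of the dataset
    (observed cells untouched; modelled variables fully filled).
    """
    aug = _make_augmenter(ds, state.variables)
    Vc = aug.istep(state.coefficients, state.residual_covariance, rng)
    theta, sigma = aug.pstep(Vc, rng)
    completed = ds.data.copy()
    completed[list(state.variables)] = Vc
    new_state = MVNState(theta, sigma, state.regressors, state.variables)
    return new_state, completed


def impute_mvn(
    ds: IncompleteDataset,
    model_vars: Sequence[str],
    settings: EngineSettings | None = None,
    nonzero_columns: Sequence[str] = (),
) -> ImputationStack:
    """Run the data-augmentation chain and collect M completed datasets.

    Starts at the EM maximiser, burns in ``settings.burn_in`` iterations,
    then stores the completed dataset of every ``settings.thin``-th
    iteration until M are collected. Deterministic given ``settings.seed``.

    ``nonzero_columns`` guards against the measure-zero event of an imputed
    cell being exactly zero in a column that will later be a divisor: the
    offending rows get one fresh I-step redraw, and a still-zero cell is an
    error rather than silently truncated (extreme-but-nonzero draws are a
    genuine feature of raw-scale passive imputation and are never altered).
    """
    settings = settings or EngineSettings()
    aug = _make_augmenter(ds, model_vars)
    rng = np.random.default_rng(settings.seed)
    theta, sigma, _ = aug.em()
    sigma = sigma + _JITTER * np.eye(aug.p)

    nz_idx = [list(model_vars).index(c) for c in nonzero_columns]
    completed: list[pd.DataFrame] = []
    Vc = None
    total = settings.burn_in + settings.m * settings.thin
    next_store = settings.burn_in + settings.thin
    for it in range(1, total + 1):
        Vc = aug.istep(theta, sigma, rng)
        theta, sigma = aug.pstep(Vc, rng)
        if it == next_store:
            next_store += settings.thin
            Vc_store = Vc
            for j in nz_idx:
                imputed_zero = np.flatnonzero((Vc_store[:, j] == 0.0) & ~aug.obs[:, j])
                if imputed_zero.size:
                    warnings.warn(
                        f"imputed value exactly zero in {model_vars[j]!r}; "
                        "redrawing the affected rows once",
                        stacklevel=2,
                    )
                    redraw = aug.istep(theta, sigma, rng, rows_filter=imputed_zero)
                    Vc_store = Vc_store.copy()
                    Vc_store[imputed_zero] = redraw[imputed_zero]
                    if (Vc_store[imputed_zero, j] == 0.0).any():
                        raise ImputationError(
                            f"imputed {model_vars[j]!r} exactly zero after redraw"
                        )
            df = ds.data.copy()
            df[list(model_vars)] = Vc_store
            completed.append(df)
    return ImputationStack(
        datasets=completed,
        strategy="mvn",
        settings=settings,
        roles=ds.roles,
        mask=ds.mask.copy(),
    )
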