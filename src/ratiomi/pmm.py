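"""Chained-equations predictive mean matching for the ratio's components.

Raw-scale passive imputation (strategy M5) can impute a denominator close
to zero, producing wildly extreme ratios. PMM removes those outliers by
donating *observed* component values: the imputation model only ranks
candidate donors, so every imputed a1 and a2 is an observed value of that
component, and every passively derived ratio lies between
(min observed a1)/(max observed a2) and (max observed a1)/(min observed a2).

Per imputation the algorithm cycles over the incomplete variables
(a1, a2, then any other incomplete covariates z). Each target is regressed
on all other modelled variables plus the encoded outcome f(y) and the
complete covariates w; regression parameters are drawn from their
noninformative-prior posterior before predictions are formed (proper MI),
the k donors with the closest predicted mean are found, one is drawn
uniformly, and its observed value is donated. After the final cycle the
ratio is derived passively as a1/a2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular

from .datamodel import IncompleteDataset
from .errors import ImputationError
from .mvn import ImputationStack, _chol_lower
from .outcomes import encode_outcome

__all__ = ["PMMSettings", "pmm_draw", "impute_pmm_passive"]


@dataclass(frozen=True)
class PMMSettings:
    """Donor count, chained-equation cycles, imputation count and seed."""

    k_donors: int = 10
    cycles: int = 10
    m: int = 5
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.k_donors < 1 or self.cycles < 1 or self.m < 2:
            raise ValueError("need k_donors >= 1, cycles >= 1, m >= 2")


def pmm_draw(
    predicted_missing: float,
    predicted_observed,
    observed_values,
    k: int,
    rng: np.random.Generator,
):
    """Donate the observed value of one of the k nearest-prediction donors.

    Distance is |predicted mean difference|; ties at the k-th position are
    all included in the donor pool, which is then sampled uniformly.
    """
    po = np.asarray(predicted_observed, dtype=float)
    ov = np.asarray(observed_values, dtype=float)
    if po.size == 0:
        raise ImputationError("no observed values to donate from")
    if po.shape != ov.shape:
        raise ValueError("predicted_observed and observed_values must align")
    if k < 1 or k > po.size:
        raise ValueError(f"k must be in [1, {po.size}], got {k}")
    d = np.abs(po - float(predicted_missing))
    kth = np.partition(d, k - 1)[k - 1]
    donors = np.flatnonzero(d <= kth)
    return float(ov[donors[rng.integers(donors.size)]])


def _bayes_lm_draw(Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator):
    """Posterior draw (beta, sigma) of a linear regression, Jeffreys prior."""
    n, q = Xo.shape
    if n <= q:
        raise ImputationError(
            f"too few observed rows ({n}) for a {q}-regressor PMM model"
        )
    XtX = Xo.T @ Xo
    L = _chol_lower(XtX)
    beta_hat = cho_solve((L, True), Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    ssr = float(resid @ resid)
    sigma2 = max(ssr, 1e-300) / rng.chisquare(n - q)
    # beta | sigma2 ~ N(beta_hat, sigma2 (X'X)^-1)
    inv_L = solve_triangular(L, np.eye(q), lower=True)
    beta = beta_hat + np.sqrt(sigma2) * (inv_L.T @ rng.standard_normal(q))
    return beta


def _match_donors(
    pred_mis: np.ndarray,
    pred_obs: np.ndarray,
    obs_vals: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised donor matching for a block of missing rows."""
    D = np.abs(pred_obs[None, :] - pred_mis[:, None])
    k = min(k, pred_obs.size)
    kth = np.partition(D, k - 1, axis=1)[:, k - 1]
    out = np.empty(pred_mis.size)
    for i in range(pred_mis.size):
        donors = np.flatnonzero(D[i] <= kth[i])
        out[i] = obs_vals[donors[rng.integers(donors.size)]]
    return out


def impute_pmm_passive(
    ds: IncompleteDataset, settings: PMMSettings | None = None
) -> ImputationStack:
    """M imputations by chained-equations PMM on (a1, a2, z), ratio passive."""
    settings = settings or PMMSettings()
    roles = ds.roles
    a1, a2, xp = roles.numerator, roles.denominator, roles.ratio
    targets = [a1, a2, *roles.incomplete_covariates]
    enc = encode_outcome(ds)
    fixed = pd.concat(
        [enc.columns, ds.data[list(roles.complete_covariates)]], axis=1
    ).to_numpy(dtype=float)

    vals = {t: ds.data[t].to_numpy(dtype=float) for t in targets}
    obs = {t: ds.mask[t].to_numpy() for t in targets}
    for t in targets:
        n_obs = int(obs[t].sum())
        if settings.k_donors > n_obs:
            raise ValueError(
                f"k_donors={settings.k_donors} exceeds the {n_obs} observed "
                f"values of {t!r}"
            )
    xp_missing = ~ds.mask[xp].to_numpy()

    root = (
        settings.seed
        if isinstance(settings.seed, np.random.SeedSequence)
        else np.random.SeedSequence(settings.seed)
    )
    datasets = []
    for child in root.spawn(settings.m):
        rng = np.random.default_rng(child)
        cur = {t: v.copy() for t, v in vals.items()}
        # initial fill: random draws from each variable's observed values
        for t in targets:
            mis = ~obs[t]
            pool = cur[t][obs[t]]
            cur[t][mis] = rng.choice(pool, size=int(mis.sum()), replace=True)
        for _ in range(settings.cycles):
            for t in targets:
                mis = ~obs[t]
                if not mis.any():
                    continue
                others = [cur[o] for o in targets if o != t]
                X = np.column_stack(
                    [np.ones(ds.n), *others, fixed]
                )
                beta = _bayes_lm_draw(X[obs[t]], cur[t][obs[t]], rng)
                pred = X @ beta
                cur[t][mis] = _match_donors(
                    pred[mis], pred[obs[t]], cur[t][obs[t]],
                    settings.k_donors, rng,
                )
        df = ds.data.copy()
        for t in targets:
            df[t] = cur[t]
        ratio = cur[a1] / cur[a2]
        df.loc[xp_missing, xp] = ratio[xp_missing]
        datasets.append(df)
    return ImputationStack(
        datasets=datasets,
        strategy="M5-PMM",
        settings=settings,
        roles=roles,
        mask=ds.mask.copy(),
    )
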