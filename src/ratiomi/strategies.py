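"""The six candidate imputation models for an incomplete ratio covariate.

Active strategies model the ratio x_p directly, optionally alongside one or
both of its components, inside the joint MVN imputation model:

* M1: (z, x_p)           -- compatible with the analysis model
* M2: (z, x_p, a1)       -- semi-compatible (a1 is auxiliary)
* M3: (z, x_p, a2)       -- semi-compatible
* M4: (z, x_p, a1, a2)   -- semi-compatible ("just another variable")

Passive strategies model the components and derive the ratio afterwards:

* M5: (z, a1, a2), x_p := a1/a2                      -- incompatible
* M6: (z, ln a1, ln a2), x_p := exp(ln a1 - ln a2)   -- incompatible

M5 is known to be dangerous when the denominator's coefficient of variation
is large (an imputed a2 near zero produces an extreme ratio with high
leverage, biasing the slope towards the null); M6 guarantees positive
imputed components and ratios. M5-PMM replaces the normal draws of M5 with
predictive-mean-matching donor values (see :mod:`ratiomi.pmm`).

The compatibility labels are the standard taxonomy: *compatible* means a
joint model implies both the imputation and the analysis model as
conditionals; *semi-compatible* means a restriction of the imputation model
is compatible; *incompatible* means no restriction is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .datamodel import ColumnRoles, IncompleteDataset
from .errors import DomainError, ImputationError
from .mvn import EngineSettings, ImputationStack, impute_mvn

__all__ = [
    "StrategySpec",
    "STRATEGY_LABELS",
    "build_strategy",
    "compatibility_class",
    "apply_passive",
    "ratio_identity_violations",
    "impute_with_strategy",
]

STRATEGY_LABELS = ("M1", "M2", "M3", "M4", "M5", "M6", "M5-PMM")

_COMPATIBILITY = {
    "M1": "compatible",
    "M2": "semi-compatible",
    "M3": "semi-compatible",
    "M4": "semi-compatible",
    "M5": "incompatible",
    "M6": "incompatible",
    # donor matching has no parametric joint model; the label is nominal,
    # inherited from the model used to rank donors
    "M5-PMM": "incompatible",
}


@dataclass(frozen=True)
class StrategySpec:
    """One imputation strategy: modelled variables, passive rule, class."""

    label: str
    modelled_vars: tuple[str, ...]
    passive_rule: str  # "none" | "ratio_from_raw" | "ratio_from_log"
    compatibility: str


def compatibility_class(label: str) -> str:
    """Relationship of the imputation model to the analysis model."""
    try:
        return _COMPATIBILITY[label]
    except KeyError:
        raise ValueError(
            f"unknown strategy {label!r}; expected one of {STRATEGY_LABELS}"
        ) from None


def log_name(column: str) -> str:
    """Name of the on-the-fly log-transformed copy of a component column."""
    return f"ln_{column}"


def build_strategy(label: str, roles: ColumnRoles) -> StrategySpec:
    """Resolve a strategy label into modelled variables and a passive rule."""
    z = roles.incomplete_covariates
    a1, a2, xp = roles.numerator, roles.denominator, roles.ratio
    table = {
        "M1": ((*z, xp), "none"),
        "M2": ((*z, xp, a1), "none"),
        "M3": ((*z, xp, a2), "none"),
        "M4": ((*z, xp, a1, a2), "none"),
        "M5": ((*z, a1, a2), "ratio_from_raw"),
        "M5-PMM": ((*z, a1, a2), "ratio_from_raw"),
        "M6": ((*z, log_name(a1), log_name(a2)), "ratio_from_log"),
    }
    if label not in table:
        raise ValueError(
            f"unknown strategy {label!r}; expected one of {STRATEGY_LABELS}"
        )
    modelled, rule = table[label]
    return StrategySpec(label, modelled, rule, _COMPATIBILITY[label])


def _with_log_components(ds: IncompleteDataset) -> IncompleteDataset:
    """Append ln(a1), ln(a2) columns (missing where the component is missing)."""
    a1, a2 = ds.roles.numerator, ds.roles.denominator
    data = ds.data.copy()
    mask = ds.mask.copy()
    for col in (a1, a2):
        vals = data[col]
        bad = mask[col] & (vals <= 0)
        if bad.any():
            raise DomainError(
                f"log-scale strategy requires positive observed {col!r}; "
                f"rows {data.index[bad].tolist()} violate this"
            )
        with np.errstate(invalid="ignore"):
            data[log_name(col)] = np.log(vals)
        mask[log_name(col)] = mask[col]
    return IncompleteDataset(data, mask, ds.roles)


def apply_passive(stack: ImputationStack, spec: StrategySpec) -> ImputationStack:
    """Derive the ratio (and raw components, for the log rule) in every imputation.

    Rows where the ratio was observed keep their observed value. For
    ``ratio_from_raw``, x_p := a1/a2; an imputed denominator exactly zero is
    an error (the engine should already have redrawn it once). For
    ``ratio_from_log``, a1 := exp(ln a1), a2 := exp(ln a2) and
    x_p := exp(ln a1 - ln a2); helper log columns are dropped.
    """
    if spec.passive_rule == "none":
        return dc_replace(stack, strategy=spec.label)
    roles = stack.roles
    a1, a2, xp = roles.numerator, roles.denominator, roles.ratio
    xp_missing = ~stack.mask[xp].to_numpy()
    a1_missing = ~stack.mask[a1].to_numpy()
    a2_missing = ~stack.mask[a2].to_numpy()
    out = []
    for df in stack.datasets:
        df = df.copy()
        if spec.passive_rule == "ratio_from_log":
            la1, la2 = df[log_name(a1)].to_numpy(), df[log_name(a2)].to_numpy()
            df.loc[a1_missing, a1] = np.exp(la1[a1_missing])
            df.loc[a2_missing, a2] = np.exp(la2[a2_missing])
            df.loc[xp_missing, xp] = np.exp(la1 - la2)[xp_missing]
            df = df.drop(columns=[log_name(a1), log_name(a2)])
        else:
            den = df[a2].to_numpy()
            if (den[a2_missing] == 0.0).any():
                raise ImputationError(
                    f"imputed denominator {a2!r} exactly zero; cannot derive ratio"
                )
            ratio = df[a1].to_numpy() / den
            df.loc[xp_missing, xp] = ratio[xp_missing]
        out.append(df)
    return ImputationStack(out, spec.label, stack.settings, roles, stack.mask)


def ratio_identity_violations(
    stack: ImputationStack, tol: float = 1e-10
) -> float:
    """Fraction of imputed-ratio rows violating x_p = a1/a2.

    Active strategies (M2-M4) draw the ratio and its components as separate
    normal coordinates and therefore do not respect the deterministic
    identity; this diagnostic reports how often it fails beyond ``tol``
    (relative), over rows where the ratio was imputed and both components
    are available in the completed data. Returns NaN when no row qualifies.
    """
    roles = stack.roles
    a1, a2, xp = roles.numerator, roles.denominator, roles.ratio
    xp_missing = ~stack.mask[xp].to_numpy()
    viol = 0
    total = 0
    for df in stack.datasets:
        av1, av2, r = (df[c].to_numpy() for c in (a1, a2, xp))
        usable = xp_missing & ~np.isnan(av1) & ~np.isnan(av2) & (av2 != 0)
        if not usable.any():
            continue
        derived = av1[usable] / av2[usable]
        rel = np.abs(r[usable] - derived) / np.maximum(np.abs(derived), 1.0)
        viol += int((rel > tol).sum())
        total += int(usable.sum())
    return viol / total if total else float("nan")


def impute_with_strategy(
    ds: IncompleteDataset,
    label: str,
    settings: EngineSettings | None = None,
    pmm_settings=None,
) -> ImputationStack:
    """Multiply impute the dataset under one named strategy.

    Dispatches M1-M6 to the MVN data-augmentation engine (with on-the-fly
    log transforms for M6 and the zero-denominator guard for M5) and
    M5-PMM to the chained-equations predictive-mean-matching routine.
    """
    if label == "M5-PMM":
        from .pmm import PMMSettings, impute_pmm_passive

        if pmm_settings is None:
            seed = settings.seed if settings is not None else None
            m = settings.m if settings is not None else 5
            pmm_settings = PMMSettings(seed=seed, m=m)
        return impute_pmm_passive(ds, pmm_settings)
    spec = build_strategy(label, ds.roles)
    work = _with_log_components(ds) if spec.passive_rule == "ratio_from_log" else ds
    nonzero = (ds.roles.denominator,) if spec.passive_rule == "ratio_from_raw" else ()
    stack = impute_mvn(work, spec.modelled_vars, settings, nonzero_columns=nonzero)
    return apply_passive(stack, spec)
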