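"""Outcome encoding for the imputation model.

The analysis-model outcome must enter the imputation model as one or more
fully observed regressors. For a continuous outcome this is the outcome
itself. For a survival outcome it is the censoring indicator together with
the Nelson-Aalen estimate of the cumulative hazard evaluated at each
subject's own (event or censoring) time, included as two separate columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import IncompleteDataset
from .errors import DomainError

__all__ = ["OutcomeEncoding", "nelson_aalen", "encode_outcome"]


@dataclass(frozen=True)
class OutcomeEncoding:
    """Fully observed columns representing the outcome, plus the family label."""

    columns: pd.DataFrame
    family: str  # "continuous" | "survival"


def nelson_aalen(times, events) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's own time.

    H(t) = sum over distinct event times s <= t of d_s / n_s, with d_s the
    number of events at s and n_s the number at risk at s. Ties contribute
    jointly (d_s >= 2); a subject censored exactly at an event time is
    counted in the risk set at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape or times.ndim != 1 or times.size == 0:
        raise ValueError("times and events must be equal-length 1-d arrays, n >= 1")
    if (times <= 0).any():
        raise DomainError("survival/censoring times must be strictly positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be coded 0/1")

    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order].astype(int)
    n = times.size
    # distinct times, events and at-risk counts at each
    uniq, first = np.unique(ts, return_index=True)
    d = np.add.reduceat(es, first)
    n_risk = n - first  # everyone with time >= uniq[k], ties included
    increments = d / n_risk
    H_at_uniq = np.cumsum(increments)
    # H at each subject's own time: all increments at times <= t_i
    idx = np.searchsorted(uniq, times, side="right") - 1
    return H_at_uniq[idx]


def encode_outcome(ds: IncompleteDataset) -> OutcomeEncoding:
    """Encode the dataset's outcome for inclusion in the imputation model."""
    roles = ds.roles
    if roles.family == "continuous":
        col = roles.outcome
        if ds.data[col].isna().any():
            raise DomainError(f"outcome column {col!r} contains missing values")
        return OutcomeEncoding(ds.data[[col]].copy(), "continuous")
    if ds.data[roles.event].isna().any() or ds.data[roles.time].isna().any():
        raise DomainError("survival outcome requires fully observed event and time")
    H = nelson_aalen(ds.data[roles.time], ds.data[roles.event])
    cols = pd.DataFrame(
        {
            roles.event: ds.data[roles.event].to_numpy(dtype=float),
            "cumulative_hazard": H,
        },
        index=ds.data.index,
    )
    return OutcomeEncoding(cols, "survival")
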