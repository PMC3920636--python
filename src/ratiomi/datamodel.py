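"""Dataset representation for regression problems with an incomplete ratio covariate.

The central object is :class:`IncompleteDataset`: a numeric table together
with an observed/missing mask and a :class:`ColumnRoles` declaration that
names the ratio ``x_p = a1 / a2``, its numerator and denominator, any other
incomplete covariates ``z``, complete covariates ``w``, and the outcome
(either a continuous ``y`` or a survival ``(time, event)`` pair).

Invariants enforced at construction:

* wherever numerator, denominator and ratio are all observed, the ratio
  equals numerator/denominator to relative tolerance 1e-10;
* the ratio is flagged missing whenever either component is missing;
* complete covariates, outcome, event and time contain no missing cells
  (fully observed outcomes are a requirement of the imputation strategies);
* observed denominators are strictly nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, ParseError, RoleError

__all__ = [
    "ColumnRoles",
    "IncompleteDataset",
    "load_dataset",
    "write_dataset",
    "missingness_pattern",
    "roles_from_file",
]

RATIO_REL_TOL = 1e-10


@dataclass(frozen=True)
class ColumnRoles:
    """Declares which column plays which part in the analysis model.

    ``outcome`` names a continuous outcome; for a survival outcome give
    ``event`` and ``time`` instead (both or neither).
    """

    numerator: str
    denominator: str
    ratio: str
    incomplete_covariates: tuple[str, ...] = ()
    complete_covariates: tuple[str, ...] = ()
    outcome: str | None = None
    event: str | None = None
    time: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "incomplete_covariates", tuple(self.incomplete_covariates)
        )
        object.__setattr__(
            self, "complete_covariates", tuple(self.complete_covariates)
        )
        core = (self.numerator, self.denominator, self.ratio)
        if len(set(core)) != 3:
            raise RoleError(
                f"numerator, denominator and ratio must be distinct, got {core}"
            )
        if (self.event is None) != (self.time is None):
            raise RoleError(
                "event and time must be given together (survival outcome) "
                "or both omitted (continuous outcome)"
            )
        if self.event is None and self.outcome is None:
            raise RoleError("an outcome column is required: outcome, or event+time")
        named = list(core) + list(self.incomplete_covariates) + list(
            self.complete_covariates
        )
        named += [c for c in (self.outcome, self.event, self.time) if c is not None]
        if len(named) != len(set(named)):
            raise RoleError(f"duplicated column in role declaration: {sorted(named)}")

    @property
    def family(self) -> str:
        """``"survival"`` if an event/time pair is declared, else ``"continuous"``."""
        return "survival" if self.event is not None else "continuous"

    @property
    def complete_columns(self) -> tuple[str, ...]:
        """Columns that must not contain missing cells."""
        cols = list(self.complete_covariates)
        cols += [c for c in (self.outcome, self.event, self.time) if c is not None]
        return tuple(cols)

    def all_columns(self) -> tuple[str, ...]:
        return (
            self.numerator,
            self.denominator,
            self.ratio,
            *self.incomplete_covariates,
            *self.complete_columns,
        )


@dataclass
class IncompleteDataset:
    """A numeric table, a per-cell observed mask and the column roles.

    ``data`` holds floats with NaN in missing cells; ``mask`` is boolean with
    True marking observed cells. Construct via :meth:`from_dataframe` (or
    :func:`load_dataset`) to have the invariants checked and the ratio
    derived/flagged; the plain constructor trusts its inputs.
    """

    data: pd.DataFrame
    mask: pd.DataFrame
    roles: ColumnRoles

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "IncompleteDataset":
        return IncompleteDataset(self.data.copy(), self.mask.copy(), self.roles)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, roles: ColumnRoles
    ) -> "IncompleteDataset":
        """Build a dataset from a DataFrame with NaN marking missing cells.

        Derives the ratio column from the components when absent, flags the
        ratio missing wherever a component is missing, cross-checks a supplied
        ratio against the derived one, and validates the invariants.
        """
        df = df.copy()
        declared = [c for c in roles.all_columns() if c != roles.ratio]
        missing_cols = [c for c in declared if c not in df.columns]
        if missing_cols:
            raise RoleError(f"declared columns absent from data: {missing_cols}")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric cell in data: {exc}") from exc

        num, den, rat = roles.numerator, roles.denominator, roles.ratio
        den_obs = df[den].notna()
        if (df.loc[den_obs, den] == 0.0).any():
            bad = df.index[den_obs & (df[den] == 0.0)].tolist()
            raise DomainError(
                f"observed denominator {den!r} is zero in rows {bad}; "
                "ratios require strictly nonzero denominators"
            )
        derived = df[num] / df[den]
        if rat in df.columns:
            both = df[rat].notna() & derived.notna()
            denom = np.maximum(np.abs(derived[both]), 1.0)
            off = np.abs(df.loc[both, rat] - derived[both]) / denom
            if (off > RATIO_REL_TOL).any():
                bad = off.index[off > RATIO_REL_TOL].tolist()
                raise DomainError(
                    f"supplied ratio column {rat!r} disagrees with "
                    f"{num}/{den} beyond tolerance in rows {bad}"
                )
        else:
            df[rat] = derived
        # ratio is missing whenever a component is missing
        df.loc[df[num].isna() | df[den].isna(), rat] = np.nan

        incomplete_bad = [
            c for c in roles.complete_columns if df[c].isna().any()
        ]
        if incomplete_bad:
            raise DomainError(
                "columns declared complete contain missing cells: "
                f"{incomplete_bad} (outcomes and complete covariates must be "
                "fully observed)"
            )
        mask = df.notna()
        return cls(df, mask, roles)


def roles_from_file(path: str | Path) -> tuple[ColumnRoles, str]:
    """Read a YAML/JSON role declaration; returns (roles, missing_token).

    Recognised keys mirror :class:`ColumnRoles` fields plus ``missing_token``
    (default ``"NA"``).
    """
    with open(path) as fh:
        cfg: Mapping = yaml.safe_load(fh)
    token = cfg.get("missing_token", "NA")
    fields = {
        k: cfg[k]
        for k in (
            "numerator",
            "denominator",
            "ratio",
            "incomplete_covariates",
            "complete_covariates",
            "outcome",
            "event",
            "time",
        )
        if k in cfg
    }
    return ColumnRoles(**fields), token


def load_dataset(
    path: str | Path,
    roles: ColumnRoles,
    missing_token: str = "NA",
    delimiter: str | None = None,
) -> IncompleteDataset:
    """Load a delimited numeric table with a header row.

    ``missing_token`` marks missing cells (default "NA"). The delimiter is
    inferred from the extension (``.tsv``/``.tab`` -> tab, otherwise comma)
    unless given. The ratio column is derived from the components when absent
    from the file; when present it is cross-checked, not overwritten.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    parsed = {}
    for col in raw.columns:
        cells = raw[col].str.strip()
        miss = (cells == missing_token) | (cells == "")
        try:
            vals = pd.to_numeric(cells.where(~miss))
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"column {col!r} contains a non-numeric cell that is not "
                f"the missing token {missing_token!r}: {exc}"
            ) from exc
        parsed[col] = vals.astype(float)
    return IncompleteDataset.from_dataframe(pd.DataFrame(parsed), roles)


def write_dataset(
    ds: IncompleteDataset,
    path: str | Path,
    missing_token: str = "NA",
    delimiter: str | None = None,
) -> None:
    """Write the dataset back to a delimited file; inverse of :func:`load_dataset`."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out = ds.data.where(ds.mask)
    out.to_csv(path, sep=delimiter, index=False, na_rep=missing_token)


def missingness_pattern(ds: IncompleteDataset) -> dict[str, int]:
    """Count rows by the reason the ratio is missing.

    Returns counts of rows with only the numerator missing, only the
    denominator missing, both components missing, and both observed; the
    four counts sum to ``ds.n``.
    """
    m1 = ~ds.mask[ds.roles.numerator].to_numpy()
    m2 = ~ds.mask[ds.roles.denominator].to_numpy()
    return {
        "numerator_only": int((m1 & ~m2).sum()),
        "denominator_only": int((~m1 & m2).sum()),
        "both": int((m1 & m2).sum()),
        "complete": int((~m1 & ~m2).sum()),
    }
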