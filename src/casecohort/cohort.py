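"""Cohort container and delimited-text I/O.

A cohort is one row per subject: an identifier, the entry offset from study
start (years), the follow-up time from study entry (years), a binary event
indicator, and a fixed-length covariate vector.  Time from study entry is
the analysis time scale throughout; the entry offset only matters for
administrative censoring under staggered entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("id", "entry", "exit", "event")


class CohortValidationError(ValueError):
    """Raised when cohort data violate a structural invariant."""


@dataclass(frozen=True)
class Cohort:
    """Per-subject survival records with covariates.

    Parameters
    ----------
    ids : array of opaque identifiers, unique.
    entry : entry time offsets from study start, in years, >= 0.
    exit : follow-up times from study entry, in years, > 0.
    event : binary event indicators.
    covariates : (n, p) matrix of covariate values.
    covariate_names : ordered labels for the p covariate columns.
    """

    ids: np.ndarray
    entry: np.ndarray
    exit: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.ids)
        cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        for name, arr in (("entry", self.entry), ("exit", self.exit), ("event", self.event)):
            if len(arr) != n:
                raise CohortValidationError(f"column '{name}' has length {len(arr)} != {n}")
        if cov.shape[0] != n:
            raise CohortValidationError(
                f"covariate matrix has {cov.shape[0]} rows for {n} subjects"
            )
        if cov.shape[1] != len(self.covariate_names):
            raise CohortValidationError(
                f"{cov.shape[1]} covariate columns but {len(self.covariate_names)} names"
            )
        if len(np.unique(self.ids)) != n:
            raise CohortValidationError("subject ids are not unique")
        if np.any(self.entry < 0):
            raise CohortValidationError("entry times must be >= 0")
        if np.any(self.exit <= 0):
            raise CohortValidationError("exit (follow-up) times must be > 0")
        if not np.all(np.isin(self.event, (0, 1))):
            bad = np.flatnonzero(~np.isin(self.event, (0, 1)))[:5]
            raise CohortValidationError(
                f"event indicator must be 0/1; offending rows (0-based): {bad.tolist()}"
            )
        if not np.all(np.isfinite(cov)):
            raise CohortValidationError("covariates contain non-finite values")
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float))
        object.__setattr__(self, "exit", np.asarray(self.exit, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def covariate(self, name: str) -> np.ndarray:
        """Return one covariate column by name."""
        try:
            j = self.covariate_names.index(name)
        except ValueError:
            raise KeyError(f"no covariate named '{name}'") from None
        return self.covariates[:, j]

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Return the (n, k) matrix for a covariate subset (default: all)."""
        if names is None:
            return self.covariates
        idx = [self.covariate_names.index(n) for n in names]
        return self.covariates[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "entry": self.entry, "exit": self.exit, "event": self.event})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariate_names: Sequence[str] | None = None) -> "Cohort":
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        if covariate_names is None:
            covariate_names = [c for c in df.columns if c not in RESERVED_COLUMNS]
        cov = df[list(covariate_names)].to_numpy(dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(len(df), -1)
        return cls(
            ids=df["id"].to_numpy(),
            entry=df["entry"].to_numpy(dtype=float),
            exit=df["exit"].to_numpy(dtype=float),
            event=df["event"].to_numpy(),
            covariates=cov,
            covariate_names=tuple(covariate_names),
        )


def read_cohort(
    path,
    sep: str = ",",
    column_map: dict[str, str] | None = None,
    covariate_names: Sequence[str] | None = None,
) -> Cohort:
    """Read a cohort from a delimited text file with a header row.

    ``column_map`` renames file columns onto the canonical names
    (``{"id": "subject", "exit": "futime", ...}`` means the file's column
    ``subject`` holds ids, etc.).  Columns not named id/entry/exit/event are
    treated as covariates unless ``covariate_names`` restricts them.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        rename = {}
        for canonical, actual in column_map.items():
            if actual not in df.columns:
                raise CohortValidationError(
                    f"configured column '{actual}' (for '{canonical}') not in file"
                )
            rename[actual] = canonical
        df = df.rename(columns=rename)
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    for col in ("entry", "exit", "event"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise CohortValidationError(
                f"non-numeric values in column '{col}' at file lines {lines}"
            )
        if coerced.isna().any():
            lines = [int(i) + 2 for i in df.index[coerced.isna()][:5]]
            raise CohortValidationError(f"missing values in column '{col}' at file lines {lines}")
        df[col] = coerced
    return Cohort.from_frame(df, covariate_names=covariate_names)


def write_cohort(cohort: Cohort, path, sep: str = ",", float_format: str = "%.17g") -> None:
    """Write a cohort to delimited text (columns id, entry, exit, event, covariates)."""
    cohort.to_frame().to_csv(path, sep=sep, index=False, float_format=float_format)
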