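"""Typed representation of partially observed causal data.

The observed data unit is ``O = (L_O, R_L1..R_Lq, R_A, R_L1*L_M1, ...,
R_Lq*L_Mq, R_A*A, Y)``: a fully observed outcome ``Y``, a partially observed
exposure ``A`` with observation indicator ``R_A``, fully observed covariates
``L_O`` and partially observed covariates ``L_M1..L_Mq`` with indicators
``R_L1..R_Lq``.  Missing cells are carried as ``NaN``; the indicators are
derived from missing-value codes at CSV ingestion and kept consistent with
the cells thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableRoles",
    "ObservedTable",
    "MissingnessSummary",
    "read_dataset",
    "write_dataset",
    "coarsen_monotone",
    "summarize_missingness",
]

DEFAULT_MISSING_CODES = ("", "NA")


@dataclass(frozen=True)
class VariableRoles:
    """Mapping from dataset columns to their causal roles.

    Parameters
    ----------
    outcome_col : name of the fully observed outcome column.
    exposure_col : name of the partially observed exposure column.
    l_o_cols : fully observed covariate columns.
    l_m_cols : partially observed covariate columns, **in analysis order**
        ``L_M1..L_Mq`` (the ordering is the analyst's choice and matters for
        the IB estimators).
    missing_codes : strings treated as absent values on CSV ingestion.
    exposure_level : optional default exposure level ``a`` of interest.
    id_col : optional identifier column; positional integers otherwise.
    """

    outcome_col: str
    exposure_col: str
    l_o_cols: tuple[str, ...] = ()
    l_m_cols: tuple[str, ...] = ()
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES
    exposure_level: float | None = None
    id_col: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "l_o_cols", tuple(self.l_o_cols))
        object.__setattr__(self, "l_m_cols", tuple(self.l_m_cols))
        object.__setattr__(self, "missing_codes", tuple(self.missing_codes))
        groups = [
            {self.outcome_col},
            {self.exposure_col},
            set(self.l_o_cols),
            set(self.l_m_cols),
        ]
        seen: set[str] = set()
        for g in groups:
            if seen & g:
                raise ValueError(f"role column sets overlap: {sorted(seen & g)}")
            seen |= g

    @property
    def q(self) -> int:
        return len(self.l_m_cols)

    @property
    def l_cols(self) -> tuple[str, ...]:
        return self.l_o_cols + self.l_m_cols


class ObservedTable:
    """A rectangular dataset of ``n`` partially observed records.

    Invariants enforced at construction: the outcome has no missing entries,
    the exposure is present iff ``r_a == 1``, covariate ``l_m[k]`` is present
    iff ``r_l[:, k] == 1``, and all indicators lie in ``{0, 1}``.
    """

    def __init__(
        self,
        y: np.ndarray,
        a: np.ndarray,
        l_o: pd.DataFrame,
        l_m: pd.DataFrame,
        r_a: np.ndarray,
        r_l: np.ndarray,
        roles: VariableRoles,
        ids: np.ndarray | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        a = np.asarray(a, dtype=float)
        r_a = np.asarray(r_a, dtype=int)
        r_l = np.asarray(r_l, dtype=int).reshape(len(y), -1)
        n = len(y)
        if n < 1:
            raise ValueError("ObservedTable requires at least one record")
        if np.isnan(y).any():
            raise ValueError("outcome has missing values")
        for arr, name in ((r_a, "r_a"), (r_l, "r_l")):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} indicators must be 0/1")
        if not ((r_a == 1) == ~np.isnan(a)).all():
            raise ValueError("exposure must be present iff r_a == 1")
        lm = l_m.to_numpy(dtype=float) if len(roles.l_m_cols) else np.empty((n, 0))
        if lm.shape[1] != r_l.shape[1]:
            raise ValueError("r_l width must match the number of l_m columns")
        if lm.size and not ((r_l == 1) == ~np.isnan(lm)).all():
            raise ValueError("l_m cells must be present iff the matching r_l == 1")
        if len(roles.l_o_cols) and np.isnan(l_o.to_numpy(dtype=float)).any():
            raise ValueError("l_o covariates must be fully observed")
        self.y = y
        self.a = a
        self.l_o = l_o.reset_index(drop=True)
        self.l_m = l_m.reset_index(drop=True)
        self.r_a = r_a
        self.r_l = r_l
        self.roles = roles
        self.ids = np.arange(n) if ids is None else np.asarray(ids)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def q(self) -> int:
        return self.r_l.shape[1]

    @property
    def r_l_joint(self) -> np.ndarray:
        """Block indicator: 1 iff every L_M coordinate is observed."""
        if self.q == 0:
            return np.ones(self.n, dtype=int)
        return self.r_l.min(axis=1)

    @property
    def complete_mask(self) -> np.ndarray:
        return (self.r_a == 1) & (self.r_l_joint == 1)

    def frame(self) -> pd.DataFrame:
        """Working DataFrame with role-named columns (NaN where unobserved)."""
        out = pd.DataFrame({self.roles.outcome_col: self.y})
        out[self.roles.exposure_col] = self.a
        for c in self.roles.l_o_cols:
            out[c] = self.l_o[c].to_numpy()
        for k, c in enumerate(self.roles.l_m_cols):
            out[c] = self.l_m[c].to_numpy()
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, roles: VariableRoles) -> "ObservedTable":
        """Build a table from a DataFrame in which missing cells are NaN."""
        missing = [c for c in (roles.outcome_col, roles.exposure_col, *roles.l_cols) if c not in df.columns]
        if missing:
            raise ValueError(f"role columns not found in data: {missing}")
        y = pd.to_numeric(df[roles.outcome_col]).to_numpy(dtype=float)
        if np.isnan(y).any():
            rows = [int(i) for i in np.flatnonzero(np.isnan(y))[:10]]
            raise ValueError(f"outcome column {roles.outcome_col!r} has missing values in rows {rows}")
        a = pd.to_numeric(df[roles.exposure_col]).to_numpy(dtype=float)
        l_o = df[list(roles.l_o_cols)].apply(pd.to_numeric)
        l_m = df[list(roles.l_m_cols)].apply(pd.to_numeric)
        r_a = (~np.isnan(a)).astype(int)
        lm = l_m.to_numpy(dtype=float) if roles.l_m_cols else np.empty((len(y), 0))
        r_l = (~np.isnan(lm)).astype(int)
        ids = df[roles.id_col].to_numpy() if roles.id_col else None
        return cls(y, a, l_o, l_m, r_a, r_l, roles, ids=ids)

    def take(self, indices: np.ndarray) -> "ObservedTable":
        """Row subset / resample (the record is the resampling unit)."""
        idx = np.asarray(indices)
        return ObservedTable(
            self.y[idx],
            self.a[idx],
            self.l_o.iloc[idx],
            self.l_m.iloc[idx],
            self.r_a[idx],
            self.r_l[idx],
            self.roles,
            ids=self.ids[idx],
        )

    def is_monotone(self, ordering: Sequence[str] | None = None) -> bool:
        """True iff ``r_l[k] = 0`` forces ``r_l[j] = 0`` for all later ``j``."""
        order = list(ordering) if ordering is not None else list(self.roles.l_m_cols)
        cols = [self.roles.l_m_cols.index(c) for c in order]
        seen_zero = np.zeros(self.n, dtype=bool)
        for k in cols:
            if (seen_zero & (self.r_l[:, k] == 1)).any():
                return False
            seen_zero |= self.r_l[:, k] == 0
        return True


@dataclass
class MissingnessSummary:
    """Per-variable missing fractions and joint missingness patterns."""

    frac_missing: dict[str, float]
    pattern_counts: dict[tuple[str, ...], int]
    monotone: bool
    n: int = 0

    @property
    def frac_any_missing(self) -> float:
        complete = self.pattern_counts.get((), 0)
        return 1.0 - complete / self.n if self.n else 0.0


# ----------------------------------------------------------------------
# operations


def read_dataset(path, roles: VariableRoles) -> ObservedTable:
    """Read a CSV file, deriving observation indicators from missing codes.

    A cell whose raw string is in ``roles.missing_codes`` is treated as
    absent; the matching indicator is set to 0.  Missing outcome values are
    a hard error, as is a non-binary outcome.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in (roles.outcome_col, roles.exposure_col, *roles.l_cols) if c not in raw.columns]
    if missing:
        raise ValueError(f"role columns not found in {path}: {missing}")
    codes = set(roles.missing_codes)
    df = raw.copy()
    for c in (roles.outcome_col, roles.exposure_col, *roles.l_cols):
        col = raw[c].where(~raw[c].isin(codes), np.nan)
        df[c] = pd.to_numeric(col)
    bad = df[roles.outcome_col].isna()
    if bad.any():
        rows = [int(i) for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise ValueError(f"missing outcome values in rows {rows}")
    yvals = set(np.unique(df[roles.outcome_col].to_numpy()))
    if not yvals <= {0.0, 1.0}:
        raise ValueError(f"outcome must be binary 0/1, found values {sorted(yvals)}")
    return ObservedTable.from_dataframe(df, roles)


def write_dataset(table: ObservedTable, path, missing_code: str = "NA") -> None:
    """Write a table back to CSV with ``missing_code`` for absent cells."""
    df = table.frame()
    if table.roles.id_col:
        df.insert(0, table.roles.id_col, table.ids)
    out = df.copy()
    for c in df.columns:
        col = df[c]
        if col.dtype.kind == "f" and np.allclose(col.dropna() % 1, 0):
            out[c] = col.map(lambda v: missing_code if pd.isna(v) else str(int(v)))
        else:
            out[c] = col.map(lambda v: missing_code if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


def coarsen_monotone(table: ObservedTable, ordering: Sequence[str] | None = None) -> ObservedTable:
    """Enforce monotone missingness along ``ordering``.

    In the output, ``L_Mk`` is treated as missing whenever any earlier-ordered
    ``L_Mj`` (j < k) is missing; the coarsened cells are dropped and all other
    fields are unchanged.  Idempotent, and a no-op on monotone tables.
    """
    order = list(ordering) if ordering is not None else list(table.roles.l_m_cols)
    if sorted(order) != sorted(table.roles.l_m_cols):
        raise ValueError(f"ordering must be a permutation of {table.roles.l_m_cols}")
    r_l = table.r_l.copy()
    l_m = table.l_m.copy()
    seen_zero = np.zeros(table.n, dtype=bool)
    for name in order:
        k = table.roles.l_m_cols.index(name)
        seen_zero |= r_l[:, k] == 0
        newly = seen_zero & (r_l[:, k] == 1)
        if newly.any():
            r_l[newly, k] = 0
            l_m.loc[newly, name] = np.nan
    return ObservedTable(table.y, table.a, table.l_o, l_m, table.r_a, r_l, table.roles, ids=table.ids)


def summarize_missingness(table: ObservedTable) -> MissingnessSummary:
    """Missing fractions, joint-missingness pattern counts, monotonicity flag."""
    roles = table.roles
    frac = {roles.exposure_col: float(np.mean(1 - table.r_a))}
    for k, c in enumerate(roles.l_m_cols):
        frac[c] = float(np.mean(1 - table.r_l[:, k]))
    names = (roles.exposure_col,) + roles.l_m_cols
    ind = np.column_stack([1 - table.r_a, 1 - table.r_l]) if table.q else (1 - table.r_a)[:, None]
    patterns: dict[tuple[str, ...], int] = {}
    for row in ind:
        key = tuple(n for n, m in zip(names, row) if m)
        patterns[key] = patterns.get(key, 0) + 1
    return MissingnessSummary(frac, patterns, monotone=table.is_monotone(), n=table.n)
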