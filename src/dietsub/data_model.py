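"""Observed-data container, validation, and empirical positivity diagnostics.

The observed unit record is O = (L, A, B, C, Y): baseline covariates L
(mixed binary/continuous), non-negative integer weekly servings of the food
to be replaced (A), the substitute food (B) and the remaining food groups
(C, possibly multivariate), and a binary outcome Y. Under the determinism
assumption, planned intake equals actual intake, so the planned-intake
variables are exposed as aliases of (A, B, C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservedDataset",
    "PositivityReport",
    "validate_dataset",
    "positivity_diagnostics",
]


@dataclass
class ObservedDataset:
    """Validated table of (L, A, B, C, Y) records.

    Attributes
    ----------
    L : pandas.DataFrame
        Baseline covariates, one row per subject (binary and/or continuous).
    A, B : numpy.ndarray of int
        Weekly servings of the food being replaced and of the substitute.
    C : pandas.DataFrame
        Non-negative integer servings of the other food groups (>= 1 column).
    Y : numpy.ndarray of int
        Binary outcome in {0, 1}.
    support_A, support_B : numpy.ndarray of int
        Finite ordered attainable values; always supersets of the observed
        unique values.
    """

    L: pd.DataFrame
    A: np.ndarray
    B: np.ndarray
    C: pd.DataFrame
    Y: np.ndarray
    support_A: np.ndarray = field(default=None)
    support_B: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int64)
        self.B = np.asarray(self.B, dtype=np.int64)
        self.Y = np.asarray(self.Y, dtype=np.int64)
        if self.support_A is None:
            self.support_A = np.unique(self.A)
        if self.support_B is None:
            self.support_B = np.unique(self.B)
        self.support_A = np.unique(np.asarray(self.support_A, dtype=np.int64))
        self.support_B = np.unique(np.asarray(self.support_B, dtype=np.int64))
        n = len(self.Y)
        if n < 1:
            raise ValueError("dataset must contain at least one record")
        for name, col in (("L", self.L), ("A", self.A), ("B", self.B), ("C", self.C)):
            if len(col) != n:
                raise ValueError(f"column block {name!r} has length {len(col)} != n={n}")
        if not set(np.unique(self.A)).issubset(self.support_A):
            raise ValueError("support_A does not cover observed values of A")
        if not set(np.unique(self.B)).issubset(self.support_B):
            raise ValueError("support_B does not cover observed values of B")

    @property
    def n(self) -> int:
        return len(self.Y)

    # planned-intake aliases: under determinism, planned == actual intake
    @property
    def planned_A(self) -> np.ndarray:
        return self.A

    @property
    def planned_B(self) -> np.ndarray:
        return self.B

    @property
    def planned_C(self) -> pd.DataFrame:
        return self.C

    def subset(self, idx) -> "ObservedDataset":
        """Row subset (supports are retained, not recomputed)."""
        idx = np.asarray(idx)
        return ObservedDataset(
            L=self.L.iloc[idx].reset_index(drop=True),
            A=self.A[idx],
            B=self.B[idx],
            C=self.C.iloc[idx].reset_index(drop=True),
            Y=self.Y[idx],
            support_A=self.support_A,
            support_B=self.support_B,
        )

    def to_frame(self) -> pd.DataFrame:
        """Single rectangular DataFrame with L, A, B, C and Y columns."""
        parts = [self.L.reset_index(drop=True)]
        parts.append(pd.Series(self.A, name="A"))
        parts.append(pd.Series(self.B, name="B"))
        parts.append(self.C.reset_index(drop=True))
        parts.append(pd.Series(self.Y, name="Y"))
        return pd.concat(parts, axis=1)

    def equals(self, other: "ObservedDataset") -> bool:
        return (
            self.L.reset_index(drop=True).equals(other.L.reset_index(drop=True))
            and np.array_equal(self.A, other.A)
            and np.array_equal(self.B, other.B)
            and self.C.reset_index(drop=True).equals(other.C.reset_index(drop=True))
            and np.array_equal(self.Y, other.Y)
            and np.array_equal(self.support_A, other.support_A)
            and np.array_equal(self.support_B, other.support_B)
        )


@dataclass
class PositivityReport:
    """Empirical check of the positivity assumption.

    The identification argument requires that any (A=0, B=b_dagger) cell
    reachable under the intervention has support in the observed data within
    each (C, L) stratum, and in particular that some individuals consume
    zero servings of A.
    """

    n_cells_checked: int
    violating_cells: list
    fraction_A_zero: float
    n_strata_skipped: int = 0

    @property
    def ok(self) -> bool:
        return len(self.violating_cells) == 0


def _check_integral(values: pd.Series, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        idx = int(np.flatnonzero(np.isnan(arr))[0])
        raise ValueError(f"missing value in column {name!r} at row {idx}")
    rounded = np.rint(arr)
    off = np.abs(arr - rounded) > 1e-9
    if off.any():
        idx = int(np.flatnonzero(off)[0])
        raise ValueError(
            f"non-integer exposure value {arr[idx]!r} in column {name!r} at row {idx}; "
            "round or bin fractional servings before validation"
        )
    if (rounded < 0).any():
        idx = int(np.flatnonzero(rounded < 0)[0])
        raise ValueError(f"negative exposure value in column {name!r} at row {idx}")
    return rounded.astype(np.int64)


def validate_dataset(
    table: pd.DataFrame,
    column_roles: Mapping[str, Sequence[str] | str],
    support_A: Sequence[int] | None = None,
    support_B: Sequence[int] | None = None,
) -> ObservedDataset:
    """Validate a rectangular record table into an :class:`ObservedDataset`.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per subject.
    column_roles : mapping
        Keys ``"L"``, ``"A"``, ``"B"``, ``"C"``, ``"Y"``. ``"L"`` and
        ``"C"`` may name one or several columns; ``"A"``, ``"B"``, ``"Y"``
        name single columns.
    support_A, support_B : sequence of int, optional
        A priori supports; must cover the observed values.

    Raises
    ------
    ValueError
        On missing values, non-integral or negative exposures (naming the
        offending column and row), or Y outside {0, 1}.
    """
    roles = dict(column_roles)
    for key in ("A", "B", "C", "Y", "L"):
        if key not in roles:
            raise ValueError(f"column_roles missing role {key!r}")

    def _cols(key: str) -> list[str]:
        v = roles[key]
        return [v] if isinstance(v, str) else list(v)

    missing = [c for k in ("L", "A", "B", "C", "Y") for c in _cols(k) if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")

    L = table[_cols("L")].copy()
    if L.isna().any().any():
        col = L.columns[L.isna().any()][0]
        idx = int(np.flatnonzero(L[col].isna())[0])
        raise ValueError(f"missing value in covariate column {col!r} at row {idx}")

    a_col = _cols("A")[0]
    b_col = _cols("B")[0]
    A = _check_integral(table[a_col], a_col)
    B = _check_integral(table[b_col], b_col)
    C = pd.DataFrame(
        {c: _check_integral(table[c], c) for c in _cols("C")},
    )

    y_col = _cols("Y")[0]
    y_raw = np.asarray(table[y_col], dtype=float)
    if np.isnan(y_raw).any():
        idx = int(np.flatnonzero(np.isnan(y_raw))[0])
        raise ValueError(f"missing value in outcome column {y_col!r} at row {idx}")
    if not np.isin(y_raw, (0.0, 1.0)).all():
        bad = int(np.flatnonzero(~np.isin(y_raw, (0.0, 1.0)))[0])
        raise ValueError(
            f"outcome column {y_col!r} must be binary in {{0,1}}; row {bad} has {y_raw[bad]!r}"
        )
    Y = y_raw.astype(np.int64)

    return ObservedDataset(
        L=L.reset_index(drop=True),
        A=A,
        B=B,
        C=C.reset_index(drop=True),
        Y=Y,
        support_A=support_A,
        support_B=support_B,
    )


def default_coarsening(data: ObservedDataset) -> pd.Series:
    """Default stratification of (C, L) for the positivity diagnostic.

    Exact levels for discrete columns; quartile bins for continuous
    covariate columns. Returns one stratum label per record.
    """
    pieces = [data.C[c].astype(str) for c in data.C.columns]
    for c in data.L.columns:
        col = data.L[c]
        vals = np.asarray(col, dtype=float)
        uniq = np.unique(vals)
        if len(uniq) <= 10 and np.allclose(vals, np.rint(vals)):
            pieces.append(col.astype(str))
        else:
            binned = pd.qcut(col, q=4, duplicates="drop")
            pieces.append(binned.astype(str))
    lab = pieces[0]
    for p in pieces[1:]:
        lab = lab.str.cat(p, sep="|")
    return lab


def positivity_diagnostics(
    data: ObservedDataset,
    x: int,
    coarsening=None,
) -> PositivityReport:
    """Empirically check positivity for the capped substitution strategy.

    For each coarsened (C, L) stratum and each intervened substitute dose
    b_dagger = min(A + B, x) occurring in that stratum, reports whether any
    record with A = 0 and B = b_dagger is observed in the stratum. Also
    reports the empirical P(A = 0); positivity requires individuals with
    A = 0 in every relevant stratum.

    Parameters
    ----------
    data : ObservedDataset
    x : int
        Positive cap on the intervened substitute dose.
    coarsening : callable, optional
        Maps the dataset to a per-record stratum label Series. Defaults to
        exact levels of discrete columns and quartiles of continuous ones.
    """
    if x < 1:
        raise ValueError("cap x must be a positive integer")
    labels = (coarsening or default_coarsening)(data)
    labels = pd.Series(np.asarray(labels, dtype=object))
    b_dagger = np.minimum(data.A + data.B, x)

    frac_a0 = float(np.mean(data.A == 0))
    violating: list[tuple[int, str]] = []
    n_checked = 0
    n_skipped = 0
    for stratum, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty groups
            n_skipped += 1
            continue
        a_s = data.A[idx]
        b_s = data.B[idx]
        bd_s = b_dagger[idx]
        observed_a0_b = set(b_s[a_s == 0].tolist())
        for bd in sorted(set(bd_s.tolist())):
            n_checked += 1
            if bd not in observed_a0_b:
                violating.append((int(bd), str(stratum)))
    if n_skipped:
        warnings.warn(f"{n_skipped} empty strata skipped in positivity diagnostic")
    return PositivityReport(
        n_cells_checked=n_checked,
        violating_cells=violating,
        fraction_A_zero=frac_a0,
        n_strata_skipped=n_skipped,
    )
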