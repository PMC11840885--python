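"""The capped substitution strategy g and its induced exposure distributions.

Strategy g replaces food A with food B: the intervened intake is A = 0 and
B = d(A, B) = min(A + B, x) for a cap x, with other food groups C left at
their natural values. This module implements the dose map d, the degenerate
intervened-exposure kernel q, the marginalized intervened pmf q-tilde, and
the inverse-probability weight

    W = I(A = 0) * qtilde(B | C, L) / ( p(A=0 | C, L) * p(B | A=0, C, L) ),

whose population mean is 1 and which identifies mu_g = E(Y_g) via E[W Y].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ObservedDataset

__all__ = [
    "InterventionSpec",
    "WeightVector",
    "substitute_dose",
    "apply_intervention",
    "q_pointmass",
    "qtilde_pmf",
    "qtilde_records",
    "substitution_weights",
]

#: floor applied to each estimated denominator density before weighting
DEFAULT_DENSITY_FLOOR = 1e-6


@dataclass(frozen=True)
class InterventionSpec:
    """Capped substitution strategy: set A to 0 and B to min(A + B, x).

    Parameters
    ----------
    x : int
        Positive cap on the intervened substitute dose. Often chosen as
        max(support of B), but may be set a priori below it.
    target_A_value : int
        Value A is set to under the strategy (fixed at 0).
    """

    x: int
    target_A_value: int = 0

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ValueError("cap x must be a positive integer")
        if self.target_A_value != 0:
            raise ValueError("only the A -> 0 substitution strategy is supported")

    def validate_against(self, data: ObservedDataset) -> None:
        if self.x > int(data.support_B.max()):
            raise ValueError(
                f"cap x={self.x} exceeds max support of B ({int(data.support_B.max())})"
            )


@dataclass
class WeightVector:
    """Per-record substitution weights and their density components."""

    W: np.ndarray
    qtilde: np.ndarray  # qtilde(B_i | C_i, L_i), zero off the intervened support
    pA0: np.ndarray  # hat p(A=0 | C_i, L_i)
    pB_obs: np.ndarray  # hat p(B=B_i | A=0, C_i, L_i)
    n_truncated: int = 0
    floor: float = DEFAULT_DENSITY_FLOOR


def substitute_dose(a: int, b: int, x: int) -> int:
    """Substitute dose d(a, b) = a + b capped at x."""
    if a < 0 or b < 0:
        raise ValueError("servings must be non-negative")
    if x < 1:
        raise ValueError("cap x must be a positive integer")
    s = a + b
    return s if s <= x else x


def apply_intervention(data: ObservedDataset, spec: InterventionSpec) -> pd.DataFrame:
    """Intervened exposures (A=0, B=min(A+B, x), C unchanged) per record."""
    b_dagger = np.minimum(data.A + data.B, spec.x)
    out = pd.DataFrame({"A_dagger": np.zeros(data.n, dtype=np.int64), "B_dagger": b_dagger})
    for c in data.C.columns:
        out[f"{c}_dagger"] = data.C[c].to_numpy()
    return out


def q_pointmass(b_dagger: int, a: int, b: int, x: int) -> int:
    """Degenerate kernel q(b_dagger | a, b): 1 iff b_dagger = min(a + b, x)."""
    if b_dagger < 0:
        raise ValueError("b_dagger must be non-negative")
    return int(b_dagger == substitute_dose(a, b, x))


def _as_pmf(p, name: str, tol: float = 1e-8) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise ValueError(f"{name} is not a normalized pmf (sum={p.sum()!r})")
    return p


def qtilde_pmf(
    b_dagger: int,
    pA,
    pB,
    x: int,
    support_A=None,
    support_B=None,
) -> float:
    """Marginalized pmf of the intervened substitute dose, q~(b_dagger).

    Marginalizes the degenerate kernel q over the natural joint law of
    (A, B) at a fixed (c, l):

        q~(b_dagger) = sum_a [ I(a <= b_dagger <= x) pB(b_dagger - a | a)
                               + I(b_dagger = x) (1 - F_B(x - a | a)) ] pA(a)

    with F_B(t | a) = P(B <= t | A=a) and F_B(t) = 0 for t < 0.

    Parameters
    ----------
    b_dagger : int in {0, ..., x}
    pA : 1-D array
        pmf of A over ``support_A``.
    pB : 2-D array, shape (len(support_A), len(support_B))
        Row ``i`` is the pmf of B given A = support_A[i].
    x : int
        Positive cap.
    support_A, support_B : sequences of int, optional
        Default to 0..len-1.
    """
    if not (0 <= b_dagger <= x):
        raise ValueError("b_dagger must lie in {0, ..., x}")
    pA = _as_pmf(pA, "pA")
    pB = np.atleast_2d(np.asarray(pB, dtype=float))
    support_A = np.arange(len(pA)) if support_A is None else np.asarray(support_A, dtype=int)
    support_B = (
        np.arange(pB.shape[1]) if support_B is None else np.asarray(support_B, dtype=int)
    )
    if pB.shape != (len(support_A), len(support_B)):
        raise ValueError("pB must have shape (len(support_A), len(support_B))")
    for i in range(pB.shape[0]):
        _as_pmf(pB[i], f"pB[{i}]")

    total = 0.0
    for i, a in enumerate(support_A):
        contrib = 0.0
        if a <= b_dagger <= x:
            j = np.flatnonzero(support_B == b_dagger - a)
            if j.size:
                contrib += pB[i, j[0]]
        if b_dagger == x:
            t = x - a
            FB = pB[i, support_B <= t].sum() if t >= 0 else 0.0
            contrib += 1.0 - FB
        total += contrib * pA[i]
    return float(total)


def qtilde_records(
    data: ObservedDataset,
    expA,
    expB,
    x: int,
) -> np.ndarray:
    """q~(b_dagger | C_i, L_i) for every record and every b_dagger in 0..x.

    Parameters
    ----------
    expA, expB : fitted exposure models
        ``expA.pmf_matrix(data)`` gives p(A = a | C_i, L_i) over support_A;
        ``expB.pmf_matrix(data, a)`` gives p(B = b | A = a, C_i, L_i) over
        support_B for a counterfactual exposure level ``a``.

    Returns
    -------
    numpy.ndarray of shape (n, x + 1), each row summing to 1.
    """
    support_A = np.asarray(expA.support, dtype=int)
    support_B = np.asarray(expB.support, dtype=int)
    PA = expA.pmf_matrix(data)  # (n, |SA|)
    n = data.n
    out = np.zeros((n, x + 1))
    for i, a in enumerate(support_A):
        PB = expB.pmf_matrix(data, a)  # (n, |SB|)
        pa = PA[:, i]
        # first term: b_dagger = a + b with a + b <= x
        for bd in range(int(a), x + 1):
            j = np.flatnonzero(support_B == bd - a)
            if j.size:
                out[:, bd] += pa * PB[:, j[0]]
        # cap term: mass of B above x - a piles at b_dagger = x
        t = x - int(a)
        FB = PB[:, support_B <= t].sum(axis=1) if t >= 0 else np.zeros(n)
        out[:, x] += pa * (1.0 - FB)
    return out


def substitution_weights(
    data: ObservedDataset,
    nuisances,
    spec: InterventionSpec,
    floor: float = DEFAULT_DENSITY_FLOOR,
) -> WeightVector:
    """Inverse-probability weights for the capped substitution strategy.

    W_i = I(A_i = 0) q~(B_i | C_i, L_i) / ( p^(A=0 | C_i, L_i) *
    p^(B = B_i | A=0, C_i, L_i) ). Records with A_i != 0 receive exactly 0
    without evaluating the denominator. Estimated denominator densities
    below ``floor`` are truncated to ``floor`` and counted.
    """
    expA, expB = nuisances.expA, nuisances.expB
    x = spec.x
    support_A = np.asarray(expA.support, dtype=int)
    support_B = np.asarray(expB.support, dtype=int)

    QT = qtilde_records(data, expA, expB, x)
    q_obs = np.zeros(data.n)
    in_range = data.B <= x
    q_obs[in_range] = QT[in_range, data.B[in_range]]

    PA = expA.pmf_matrix(data)
    j0 = np.flatnonzero(support_A == 0)
    if not j0.size:
        raise ValueError("support of A does not contain 0; strategy undefined")
    pA0 = PA[:, j0[0]]
    PB0 = expB.pmf_matrix(data, 0)
    col = np.searchsorted(support_B, data.B)
    col_ok = (col < len(support_B)) & (support_B[np.minimum(col, len(support_B) - 1)] == data.B)
    pB_obs = np.where(col_ok, PB0[np.arange(data.n), np.minimum(col, len(support_B) - 1)], 0.0)

    a0 = data.A == 0
    n_trunc = int(np.sum(a0 & ((pA0 < floor) | (pB_obs < floor))))
    denom = np.maximum(pA0, floor) * np.maximum(pB_obs, floor)
    W = np.zeros(data.n)
    W[a0] = q_obs[a0] / denom[a0]
    return WeightVector(W=W, qtilde=q_obs, pA0=pA0, pB_obs=pB_obs, n_truncated=n_trunc, floor=floor)
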