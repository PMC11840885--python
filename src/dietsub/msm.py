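"""Working marginal-structural-model projections of E(Y_g | Z).

A working model g(Z; theta) = expit(s(Z)' theta) summarizes how the mean
counterfactual outcome varies across subpopulations defined by effect
modifiers Z (a subvector or transformation of the baseline covariates L).
The target is the least-false parameter: the projection of the true
E(Y_g | Z) onto the working model under the logistic quasi-likelihood,
characterized by

    0 = E[ s(Z) ( xi(L) - expit(s(Z)' theta) ) ],   xi(L) = E(Y_g | L),

which is well-defined whether or not the working model is correct. Three
estimators are provided (outcome-regression projection, weighted logistic
IPW, and a targeted estimator solving the empirical efficient-influence
equation), plus the sandwich covariance

    C^-1 Pn[ s(Z) s(Z)' phi~^2 ] C^-T / n,   C = Pn[ s(Z) s(Z)' g (1-g) ],
    phi~ = W (Y - m) + m(0, B_dagger, C, L) - g(Z; theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import patsy
from scipy.special import expit, logit

from ._optim import solve_weighted_logistic_score
from .data_model import ObservedDataset
from .estimators import Z975, _b_dagger
from .intervention import (
    DEFAULT_DENSITY_FLOOR,
    InterventionSpec,
    WeightVector,
    substitution_weights,
)
from .nuisance import NuisanceSet

__all__ = ["MSMSpec", "MSMEstimate", "msm_ore", "msm_ipw", "msm_tmle", "msm_sandwich"]


@dataclass(frozen=True)
class MSMSpec:
    """Design of the working model expit(s(Z)' theta).

    ``formula`` is a Wilkinson formula over baseline covariate names, e.g.
    ``"1 + L2"`` gives s(Z) = (1, L2)'. The link is fixed at inverse-logit.
    """

    formula: str = "1"

    def design_matrix(self, data: ObservedDataset) -> np.ndarray:
        S = np.asarray(
            patsy.dmatrix(self.formula, data.L, return_type="dataframe"), dtype=float
        )
        if np.linalg.matrix_rank(S) < S.shape[1]:
            raise ValueError(
                f"MSM design {self.formula!r} is rank-deficient on the data"
            )
        return S


@dataclass
class MSMEstimate:
    """Least-false parameter estimate with sandwich covariance."""

    theta: np.ndarray
    covariance: np.ndarray
    if_contributions: np.ndarray  # n x p stacked influence-function terms
    estimator: str
    epsilon: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        # tiny negative diagonals can arise from round-off when residuals ~ 0
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def ci(self, level_z: float = Z975) -> np.ndarray:
        se = self.se
        return np.column_stack([self.theta - level_z * se, self.theta + level_z * se])


def _score_sandwich(S: np.ndarray, phi: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C^-1 Pn[s s' phi^2] C^-T / n with C = Pn[s s' g(1-g)]; also the IF rows."""
    n = S.shape[0]
    C = (S * (g * (1.0 - g))[:, None]).T @ S / n
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular derivative matrix C; check the MSM design rank") from exc
    meat = (S * (phi**2)[:, None]).T @ S / n
    cov = Cinv @ meat @ Cinv.T / n
    if_rows = (S * phi[:, None]) @ Cinv.T
    return 0.5 * (cov + cov.T), if_rows


def msm_ore(
    data: ObservedDataset,
    outcome_model,
    msm: MSMSpec,
    spec: InterventionSpec,
) -> MSMEstimate:
    """Projection of the outcome-regression augmentation onto the MSM.

    theta solves 0 = Pn[ s(Z) ( m(0, B_dagger, C, L) - expit(s(Z)'theta) ) ]
    by Newton iteration. The covariance uses the corresponding estimating
    equation with the outcome fit treated as fixed (naive).
    """
    S = msm.design_matrix(data)
    m_int = outcome_model.predict(data, a=0, b=_b_dagger(data, spec))
    theta, norm, n_iter = solve_weighted_logistic_score(S, m_int)
    g = expit(S @ theta)
    cov, if_rows = _score_sandwich(S, m_int - g, g)
    return MSMEstimate(
        theta=theta, covariance=cov, if_contributions=if_rows, estimator="msm_ore",
        diagnostics={"se_flavor": "naive_score", "score_norm": norm, "iterations": n_iter},
    )


def msm_ipw(
    data: ObservedDataset,
    expA,
    expB,
    msm: MSMSpec,
    spec: InterventionSpec,
    weights: WeightVector | None = None,
    floor: float = DEFAULT_DENSITY_FLOOR,
) -> MSMEstimate:
    """Weighted-logistic IPW fit of the MSM.

    theta solves 0 = Pn[ s(Z) W ( Y - expit(s(Z)'theta) ) ]. Note the root
    is invariant to rescaling of W, so the plain and self-normalized
    weighted scores coincide. Covariance from the weighted estimating
    equation with exposure models treated as fixed (naive).
    """
    if weights is None:
        weights = substitution_weights(
            data, SimpleNamespace(expA=expA, expB=expB), spec, floor=floor
        )
    W = weights.W
    if W.sum() <= 0:
        raise ValueError("no records with A=0 or weights all truncated to zero")
    S = msm.design_matrix(data)
    theta, norm, n_iter = solve_weighted_logistic_score(S, data.Y, w=W)
    g = expit(S @ theta)
    n = data.n
    C = (S * (W * g * (1.0 - g))[:, None]).T @ S / n
    Cinv = np.linalg.inv(C)
    phi = W * (data.Y - g)
    meat = (S * (phi**2)[:, None]).T @ S / n
    cov = Cinv @ meat @ Cinv.T / n
    if_rows = (S * phi[:, None]) @ Cinv.T
    return MSMEstimate(
        theta=theta, covariance=0.5 * (cov + cov.T), if_contributions=if_rows,
        estimator="msm_ipw",
        diagnostics={"se_flavor": "naive_score", "score_norm": norm,
                     "iterations": n_iter, "n_truncated": weights.n_truncated},
    )


def msm_tmle(
    data: ObservedDataset,
    nuisances: NuisanceSet,
    msm: MSMSpec,
    spec: InterventionSpec,
    weights: WeightVector | None = None,
    floor: float = DEFAULT_DENSITY_FLOOR,
) -> MSMEstimate:
    """Targeted estimator of the least-false MSM parameter.

    (1) p-dimensional logistic fluctuation of Y with offset logit(m),
    covariates s(Z) and weights W, giving epsilon in R^p;
    (2) updated fit m* = expit(logit m + s(Z)'epsilon);
    (3) theta solves the projection score Pn[s(Z)(m*(0, B_dagger, C, L) -
    expit(s(Z)'theta))] = 0. At the solution both components of the
    efficient-influence equation vanish empirically. Covariance via
    :func:`msm_sandwich` with the updated fit.
    """
    if weights is None:
        weights = substitution_weights(data, nuisances, spec, floor=floor)
    W = weights.W
    if W.sum() <= 0:
        raise ValueError("no records with A=0 or weights all truncated to zero")
    S = msm.design_matrix(data)
    m_obs = nuisances.outcome.predict(data)
    m_int = nuisances.outcome.predict(data, a=0, b=_b_dagger(data, spec))
    eps, fluct_norm, _ = solve_weighted_logistic_score(
        S, data.Y, w=W, offset=logit(m_obs)
    )
    shift = S @ eps
    m_obs_star = expit(logit(m_obs) + shift)
    m_int_star = expit(logit(m_int) + shift)
    theta, proj_norm, n_iter = solve_weighted_logistic_score(S, m_int_star)
    cov, if_rows = msm_sandwich(
        data, nuisances, msm, theta, spec,
        weights=weights, m_obs=m_obs_star, m_int=m_int_star, return_if=True,
    )
    return MSMEstimate(
        theta=theta, covariance=cov, if_contributions=if_rows, estimator="msm_tmle",
        epsilon=eps,
        diagnostics={
            "se_flavor": "eif_sandwich",
            "fluctuation_score_norm": fluct_norm,
            "projection_score_norm": proj_norm,
            "iterations": n_iter,
            "n_truncated": weights.n_truncated,
        },
    )


def msm_sandwich(
    data: ObservedDataset,
    nuisances: NuisanceSet,
    msm: MSMSpec,
    theta: np.ndarray,
    spec: InterventionSpec,
    weights: WeightVector | None = None,
    m_obs: np.ndarray | None = None,
    m_int: np.ndarray | None = None,
    return_if: bool = False,
):
    """Sandwich covariance of theta from the efficient-influence residual.

    phi~_i = W_i (Y_i - m(A_i, B_i, C_i, L_i)) + m(0, B_dagger_i, C_i, L_i)
    - expit(s(Z_i)'theta). For ORE/IPW-fitted theta this assumes the
    corresponding estimating equation; it is exact for the targeted fit.
    """
    if weights is None:
        weights = substitution_weights(data, nuisances, spec)
    if m_obs is None:
        m_obs = nuisances.outcome.predict(data)
    if m_int is None:
        m_int = nuisances.outcome.predict(data, a=0, b=_b_dagger(data, spec))
    S = msm.design_matrix(data)
    theta = np.asarray(theta, dtype=float)
    g = expit(S @ theta)
    phi = weights.W * (data.Y - m_obs) + m_int - g
    cov, if_rows = _score_sandwich(S, phi, g)
    return (cov, if_rows) if return_if else cov
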