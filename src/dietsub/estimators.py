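"""Scalar-estimand estimators: ORE, IPW and TMLE with EIF-based inference.

The estimand is mu_g = E(Y_g), the mean counterfactual outcome under the
capped substitution strategy, and the contrast Delta = E(Y) - E(Y_g). The
efficient influence function is

    phi_eff(O) = W * (Y - m(A, B, C, L)) + m(0, B_dagger, C, L) - mu_g

with W the substitution weight and B_dagger = min(A + B, x). TMLE updates
the outcome fit by a one-parameter logistic fluctuation (clever covariate
used as a weight) so that the empirical mean of phi_eff is exactly zero; it
is consistent if either the outcome regression or the joint exposure models
are correctly specified (double robustness), and its sandwich standard
error is the sample SD of phi_eff over sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
from scipy.special import expit, logit

from ._optim import solve_weighted_logistic_score
from .data_model import ObservedDataset
from .intervention import (
    DEFAULT_DENSITY_FLOOR,
    InterventionSpec,
    WeightVector,
    substitution_weights,
)
from .nuisance import NuisanceSet

__all__ = ["ScalarEstimate", "ore", "ipw", "tmle", "eif_values", "contrast", "bootstrap_se"]

Z975 = 1.959963984540054


@dataclass
class ScalarEstimate:
    """Point estimate, influence-function values and Wald inference for mu_g."""

    mu_g: float
    se_mu: float
    ci_mu: tuple[float, float]
    if_values: np.ndarray
    estimator: str
    epsilon: float | None = None
    delta: float | None = None
    se_delta: float | None = None
    ci_delta: tuple[float, float] | None = None
    if_values_delta: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.if_values)


def _wald(point: float, if_values: np.ndarray) -> tuple[float, tuple[float, float]]:
    n = len(if_values)
    se = float(np.std(if_values, ddof=1) / np.sqrt(n))
    return se, (point - Z975 * se, point + Z975 * se)


def _b_dagger(data: ObservedDataset, spec: InterventionSpec) -> np.ndarray:
    return np.minimum(data.A + data.B, spec.x)


def ore(data: ObservedDataset, outcome_model, spec: InterventionSpec) -> ScalarEstimate:
    """Outcome-regression estimator: plug-in mean of m(0, B_dagger, C, L).

    The reported standard error treats the fitted outcome regression as
    fixed and is labelled naive; use :func:`bootstrap_se` for inference
    that accounts for nuisance estimation.
    """
    m_int = outcome_model.predict(data, a=0, b=_b_dagger(data, spec))
    mu = float(np.mean(m_int))
    if_vals = m_int - mu
    se, ci = _wald(mu, if_vals)
    return ScalarEstimate(
        mu_g=mu, se_mu=se, ci_mu=ci, if_values=if_vals, estimator="ore",
        diagnostics={"se_flavor": "naive"},
    )


def ipw(
    data: ObservedDataset,
    expA,
    expB,
    spec: InterventionSpec,
    weights: WeightVector | None = None,
    floor: float = DEFAULT_DENSITY_FLOOR,
) -> ScalarEstimate:
    """Hajek-type inverse-probability-weighted estimator.

    Solves 0 = Pn[ W (Y - mu) ], i.e. mu = sum(W Y) / sum(W). The standard
    error comes from the estimating-equation influence function
    W (Y - mu) / mean(W) with the exposure models treated as fixed (naive).
    """
    if weights is None:
        weights = substitution_weights(
            data, SimpleNamespace(expA=expA, expB=expB), spec, floor=floor
        )
    W = weights.W
    sw = W.sum()
    if sw <= 0:
        raise ValueError("no records with A=0 or weights all truncated to zero")
    mu = float(np.sum(W * data.Y) / sw)
    if_vals = W * (data.Y - mu) / np.mean(W)
    se, ci = _wald(mu, if_vals)
    return ScalarEstimate(
        mu_g=mu, se_mu=se, ci_mu=ci, if_values=if_vals, estimator="ipw",
        diagnostics={"se_flavor": "naive", "n_truncated": weights.n_truncated,
                     "mean_weight": float(np.mean(W))},
    )


def eif_values(
    data: ObservedDataset,
    nuisances: NuisanceSet,
    spec: InterventionSpec,
    mu: float,
    weights: WeightVector | None = None,
    m_obs: np.ndarray | None = None,
    m_int: np.ndarray | None = None,
) -> np.ndarray:
    """Per-record efficient influence function values at the given mu.

    The weighted residual uses the outcome fit at the OBSERVED exposures;
    the augmentation term evaluates it at the intervened (0, B_dagger).
    """
    if weights is None:
        weights = substitution_weights(data, nuisances, spec)
    if m_obs is None:
        m_obs = nuisances.outcome.predict(data)
    if m_int is None:
        m_int = nuisances.outcome.predict(data, a=0, b=_b_dagger(data, spec))
    return weights.W * (data.Y - m_obs) + m_int - mu


def tmle(
    data: ObservedDataset,
    nuisances: NuisanceSet,
    spec: InterventionSpec,
    weights: WeightVector | None = None,
    floor: float = DEFAULT_DENSITY_FLOOR,
) -> ScalarEstimate:
    """Targeted maximum likelihood estimator of mu_g.

    Steps: (1) substitution weights W; (2) intercept-only logistic
    fluctuation of Y with offset logit(m) and weights W, giving epsilon;
    (3) updated fit m* = expit(logit m + epsilon); (4) mu = Pn m*(0,
    B_dagger, C, L); (5) influence values from the EIF at (m*, mu), whose
    empirical mean is zero by construction of epsilon.
    """
    if weights is None:
        weights = substitution_weights(data, nuisances, spec, floor=floor)
    W = weights.W
    if W.sum() <= 0:
        raise ValueError("no records with A=0 or weights all truncated to zero")
    m_obs = nuisances.outcome.predict(data)
    m_int = nuisances.outcome.predict(data, a=0, b=_b_dagger(data, spec))
    eps_vec, score_norm, n_iter = solve_weighted_logistic_score(
        np.ones((data.n, 1)), data.Y, w=W, offset=logit(m_obs)
    )
    eps = float(eps_vec[0])
    m_obs_star = expit(logit(m_obs) + eps)
    m_int_star = expit(logit(m_int) + eps)
    mu = float(np.mean(m_int_star))
    if_vals = eif_values(
        data, nuisances, spec, mu, weights=weights, m_obs=m_obs_star, m_int=m_int_star
    )
    se, ci = _wald(mu, if_vals)
    return ScalarEstimate(
        mu_g=mu, se_mu=se, ci_mu=ci, if_values=if_vals, estimator="tmle",
        epsilon=eps,
        diagnostics={
            "se_flavor": "eif_sandwich",
            "n_truncated": weights.n_truncated,
            "fluctuation_score_norm": score_norm,
            "fluctuation_iterations": n_iter,
            "mean_eif": float(np.mean(if_vals)),
        },
    )


def contrast(data: ObservedDataset, est: ScalarEstimate) -> ScalarEstimate:
    """Populate the risk-difference fields Delta = E(Y) - mu_g.

    The per-record influence function for Delta is (Y_i - mean(Y)) minus
    the influence function for mu_g.
    """
    ybar = float(np.mean(data.Y))
    delta = ybar - est.mu_g
    if_delta = (data.Y - ybar) - est.if_values
    se, ci = _wald(delta, if_delta)
    est.delta = delta
    est.se_delta = se
    est.ci_delta = ci
    est.if_values_delta = if_delta
    return est


def bootstrap_se(
    data: ObservedDataset,
    estimate_fn,
    n_resamples: int = 500,
    seed: int = 0,
) -> dict:
    """Nonparametric bootstrap SEs for mu_g (and Delta when populated).

    ``estimate_fn`` maps a resampled :class:`ObservedDataset` to a
    :class:`ScalarEstimate`; it should refit all nuisances inside, so the
    bootstrap reflects their sampling variability (recommended for the
    naive ORE/IPW standard errors).
    """
    rng = np.random.default_rng(seed)
    mus, deltas = [], []
    for _ in range(n_resamples):
        idx = rng.integers(0, data.n, size=data.n)
        est = estimate_fn(data.subset(idx))
        mus.append(est.mu_g)
        if est.delta is not None:
            deltas.append(est.delta)
    out = {"se_mu": float(np.std(mus, ddof=1)), "n_resamples": n_resamples}
    if deltas:
        out["se_delta"] = float(np.std(deltas, ddof=1))
    return out
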