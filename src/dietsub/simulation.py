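"""Synthetic data generation, numerical oracles, and the replication harness.

Two data-generating processes are implemented. Both share the structure of
a latent uniform "dietary preference" factor U that jointly drives three
discrete weekly-servings exposures, each Binomial(3, expit(.)) given
(L, U), and a Bernoulli outcome whose true regression depends only on the
observed (A, B, C, L) — so the outcome regression is estimable while the
exposure pmfs, marginally over U, are not Binomial in the observed
covariates.

Study 1 (binary covariate):
    U ~ Unif[0,1], L ~ Ber(0.5),
    A ~ Bin(3, expit(-2 + L + U)), B ~ Bin(3, expit(1 - 2L + U)),
    C ~ Bin(3, expit(-1 + L + U)), Y ~ Ber(expit(-1 - A + B + C - 2L)).
    MSM modifier Z = L.

Study 2 (mixed covariates):
    L1 ~ Ber(0.5), L2 ~ Unif[0,2], U ~ Unif[0,1],
    A ~ Bin(3, expit(-2 + 0.75 L1 + 0.5 L2 + U)),
    B ~ Bin(3, expit(-1 + 0.5 L1 - 0.25 exp(L2) + U)),
    C ~ Bin(3, expit(-1 + L1 + U)),
    Y ~ Ber(expit(-1 - A + B + C - 2 L1 + L2 - 0.25 exp(L2) + 0.25 L1 L2)).
    MSM modifier Z = L2.

The substitution cap is x = max support of B = 3 in both studies.

The deterministic oracles compute the true mu_g = E(Y_g), E(Y), and the
least-false MSM parameters by exact enumeration of (A, B, C) in {0..3}^3
with Gauss-Legendre quadrature over U (and L2), cross-checked by
independent brute-force Monte-Carlo counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom

from ._optim import solve_weighted_logistic_score
from .data_model import ObservedDataset
from .estimators import ipw, ore, tmle
from .intervention import InterventionSpec, substitution_weights
from .msm import MSMSpec, msm_ipw, msm_ore, msm_tmle
from .nuisance import crossfit_nuisances

__all__ = [
    "DGPSpec",
    "SimulationResult",
    "generate_study1",
    "generate_study2",
    "scenario_specs",
    "msm_design",
    "run_replications",
    "least_false_oracle",
    "true_mu_oracle",
    "mc_least_false",
    "mc_true_mu",
]

SUPPORT = np.arange(4)  # exposures live on {0, 1, 2, 3}
CAP_X = 3  # x = max support of B
SCENARIOS = ("correct", "mis_outcome", "mis_exposure")


@dataclass(frozen=True)
class DGPSpec:
    """Descriptor of one simulation study's data-generating process."""

    study: int
    n: int
    seed: object
    msm_formula: str
    cap_x: int = CAP_X

    @classmethod
    def for_study(cls, study: int, n: int, seed) -> "DGPSpec":
        return cls(study=study, n=n, seed=seed, msm_formula=msm_design(study))


def _check_study(study: int) -> None:
    if study not in (1, 2):
        raise ValueError(f"study must be 1 or 2, got {study!r}")


def msm_design(study: int) -> str:
    """Default working-model design formula for each study's modifier."""
    _check_study(study)
    return "1 + L" if study == 1 else "1 + L2"


# ---------------------------------------------------------------------------
# true structural functions
# ---------------------------------------------------------------------------


def _m_true(study: int, a, b, c, cov):
    """True outcome regression E(Y | A=a, B=b, C=c, L) — no U term."""
    if study == 1:
        return expit(-1.0 - a + b + c - 2.0 * cov["L"])
    L1, L2 = cov["L1"], cov["L2"]
    return expit(-1.0 - a + b + c - 2.0 * L1 + L2 - 0.25 * np.exp(L2) + 0.25 * L1 * L2)


def _exposure_probs(study: int, cov, u):
    if study == 1:
        L = cov["L"]
        return (
            expit(-2.0 + L + u),
            expit(1.0 - 2.0 * L + u),
            expit(-1.0 + L + u),
        )
    L1, L2 = cov["L1"], cov["L2"]
    return (
        expit(-2.0 + 0.75 * L1 + 0.5 * L2 + u),
        expit(-1.0 + 0.5 * L1 - 0.25 * np.exp(L2) + u),
        expit(-1.0 + L1 + u),
    )


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------


def _finalize(L: pd.DataFrame, A, B, C, Y) -> ObservedDataset:
    return ObservedDataset(
        L=L,
        A=A,
        B=B,
        C=pd.DataFrame({"C": C}),
        Y=Y,
        support_A=SUPPORT,
        support_B=SUPPORT,
    )


def generate_study1(n: int, seed) -> ObservedDataset:
    """Draw n records from the study-1 process (binary covariate L).

    The latent factor U is drawn internally and never emitted.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    L = rng.binomial(1, 0.5, size=n)
    cov = {"L": L}
    pa, pb, pc = _exposure_probs(1, cov, u)
    A = rng.binomial(3, pa)
    B = rng.binomial(3, pb)
    C = rng.binomial(3, pc)
    Y = rng.binomial(1, _m_true(1, A, B, C, cov))
    return _finalize(pd.DataFrame({"L": L}), A, B, C, Y)


def generate_study2(n: int, seed) -> ObservedDataset:
    """Draw n records from the study-2 process (mixed covariates L1, L2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    L1 = rng.binomial(1, 0.5, size=n)
    L2 = rng.uniform(0.0, 2.0, size=n)
    cov = {"L1": L1, "L2": L2}
    pa, pb, pc = _exposure_probs(2, cov, u)
    A = rng.binomial(3, pa)
    B = rng.binomial(3, pb)
    C = rng.binomial(3, pc)
    Y = rng.binomial(1, _m_true(2, A, B, C, cov))
    return _finalize(pd.DataFrame({"L1": L1, "L2": L2}), A, B, C, Y)


def _generate(study: int, n: int, seed) -> ObservedDataset:
    _check_study(study)
    return generate_study1(n, seed) if study == 1 else generate_study2(n, seed)


# ---------------------------------------------------------------------------
# nuisance learner specifications per scenario
# ---------------------------------------------------------------------------


def scenario_specs(study: int, scenario: str) -> dict:
    """Nuisance learner specifications for a simulation arm.

    Study 1 has three arms: ``correct`` (true-form logistic outcome model;
    saturated empirical exposure pmfs over the exact discrete strata),
    ``mis_outcome`` (outcome working model with terms A, B:L, C:L only) and
    ``mis_exposure`` (Binomial-logistic exposure models dropping L). Study 2
    uses the flexible learners (gradient-boosted outcome, spline-basis
    multinomial exposures) in its single ``correct`` arm.
    """
    _check_study(study)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if study == 1:
        correct_outcome = "A + B + C + L"
        saturated = {"backend": "saturated"}
        if scenario == "correct":
            return {"outcome": correct_outcome, "expA": saturated, "expB": saturated}
        if scenario == "mis_outcome":
            return {"outcome": "A + B:L + C:L", "expA": saturated, "expB": saturated}
        return {
            "outcome": correct_outcome,
            "expA": {"backend": "binomial", "formula": "C"},
            "expB": {"backend": "binomial", "formula": "A + C"},
        }
    if scenario != "correct":
        raise ValueError(
            "study 2 has no printed parametric misspecification arms; "
            "use scenario='correct' (flexible learners)"
        )
    return {
        "outcome": {"backend": "gbt"},
        "expA": {"backend": "multinomial_spline"},
        "expB": {"backend": "multinomial_spline"},
    }


# ---------------------------------------------------------------------------
# deterministic oracles: enumeration + Gauss-Legendre quadrature
# ---------------------------------------------------------------------------


def _gl_nodes(n_nodes: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    t, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 0.5 * (hi - lo)
    return lo + half * (t + 1.0), w * half / (hi - lo)  # weights integrate a density


def _xi_table(study: int, n_nodes: int):
    """Exact-enumeration table of xi(L) = E[m(0, min(A+B,3), C, L) | L].

    Returns (Z, wZ, xi, ey): the MSM modifier values, their probability
    weights, xi(L), and the analogous E(Y | L) at each covariate point.
    """
    if n_nodes < 16:
        raise ValueError("need at least 16 quadrature nodes for oracle accuracy")
    u, wu = _gl_nodes(n_nodes, 0.0, 1.0)
    a_, b_, c_ = np.meshgrid(SUPPORT, SUPPORT, SUPPORT, indexing="ij")
    bd = np.minimum(a_ + b_, CAP_X)

    def cell(cov):
        pa, pb, pc = _exposure_probs(study, cov, u[:, None])
        # (n_nodes, 4) pmf matrices for each exposure
        PA = binom.pmf(SUPPORT[None, :], 3, pa)
        PB = binom.pmf(SUPPORT[None, :], 3, pb)
        PC = binom.pmf(SUPPORT[None, :], 3, pc)
        joint = PA[:, a_.ravel()] * PB[:, b_.ravel()] * PC[:, c_.ravel()]
        m_int = _m_true(study, 0, bd, c_, cov).ravel()
        m_nat = _m_true(study, a_, b_, c_, cov).ravel()
        return float(wu @ (joint @ m_int)), float(wu @ (joint @ m_nat))

    if study == 1:
        Z = np.array([0.0, 1.0])
        wZ = np.array([0.5, 0.5])
        vals = [cell({"L": L}) for L in (0, 1)]
    else:
        l2, wl2 = _gl_nodes(n_nodes, 0.0, 2.0)
        Z, wZ, vals = [], [], []
        for L1 in (0, 1):
            for L2, w2 in zip(l2, wl2):
                Z.append(L2)
                wZ.append(0.5 * w2)
                vals.append(cell({"L1": L1, "L2": np.float64(L2)}))
        Z, wZ = np.array(Z), np.array(wZ)
    xi = np.array([v[0] for v in vals])
    ey = np.array([v[1] for v in vals])
    return Z, wZ, xi, ey


def true_mu_oracle(study: int, n_nodes: int = 96) -> tuple[float, float]:
    """True (mu_g, E(Y)) by enumeration plus quadrature.

    The quadrature error is checked by node doubling (< 1e-8 required).
    """
    _check_study(study)

    def vals(k):
        _, wZ, xi, ey = _xi_table(study, k)
        return float(wZ @ xi), float(wZ @ ey)

    mu, ey = vals(n_nodes)
    mu2, ey2 = vals(2 * n_nodes)
    if abs(mu - mu2) > 1e-8 or abs(ey - ey2) > 1e-8:
        raise RuntimeError(
            f"quadrature not converged at {n_nodes} nodes: |d mu|={abs(mu - mu2):.2e}"
        )
    return mu2, ey2


def least_false_oracle(study: int, n_nodes: int = 96) -> tuple[np.ndarray, float]:
    """Least-false MSM parameters by solving the population score equation.

    Solves 0 = E[ s(Z) ( xi(L) - expit(s(Z)'theta) ) ] with s(Z) = (1, Z)',
    where the expectation is evaluated on the enumeration/quadrature grid.
    Returns (theta, achieved score norm); the norm is below 1e-12.
    """
    _check_study(study)
    Z, wZ, xi, _ = _xi_table(study, n_nodes)
    S = np.column_stack([np.ones_like(Z), Z])
    theta, norm, _ = solve_weighted_logistic_score(S, xi, w=wZ * len(wZ), tol=1e-13)
    return theta, norm


# ---------------------------------------------------------------------------
# true ("oracle") nuisance models, U marginalized out by quadrature
# ---------------------------------------------------------------------------


def _cov_dict(study: int, data: ObservedDataset) -> dict:
    if study == 1:
        return {"L": data.L["L"].to_numpy(dtype=float)}
    return {
        "L1": data.L["L1"].to_numpy(dtype=float),
        "L2": data.L["L2"].to_numpy(dtype=float),
    }


class TrueOutcomeModel:
    """The data-generating outcome regression (exact, no estimation)."""

    def __init__(self, study: int):
        _check_study(study)
        self.study = study
        self.descriptor = {"backend": "oracle", "study": study}

    def predict(self, data: ObservedDataset, a=None, b=None) -> np.ndarray:
        A = np.broadcast_to(np.asarray(data.A if a is None else a), (data.n,))
        B = np.broadcast_to(np.asarray(data.B if b is None else b), (data.n,))
        C = data.C["C"].to_numpy()
        return _m_true(self.study, A, B, C, _cov_dict(self.study, data))


class _TrueExposureBase:
    """Exact conditional exposure pmfs with U integrated out by quadrature.

    A, B and C are conditionally independent Binomials given (L, U), so
    e.g. p(a | c, l) = Int PA(a|l,u) PC(c|l,u) du / Int PC(c|l,u) du.
    """

    support = SUPPORT

    def __init__(self, study: int, n_nodes: int = 64):
        _check_study(study)
        self.study = study
        self.u, self.wu = _gl_nodes(n_nodes, 0.0, 1.0)
        self.descriptor = {"backend": "oracle", "study": study}

    def _binom_weights(self, data: ObservedDataset):
        cov = _cov_dict(self.study, data)
        pa, pb, pc = _exposure_probs(self.study, cov, self.u[:, None])
        return pa, pb, pc  # each (nodes, n)


class TrueExposureModelA(_TrueExposureBase):
    conditions_on_A = False

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        pa, _, pc = self._binom_weights(data)
        PC = binom.pmf(data.C["C"].to_numpy()[None, :], 3, pc)
        denom = self.wu @ PC
        out = np.empty((data.n, len(self.support)))
        for j, val in enumerate(self.support):
            out[:, j] = (self.wu @ (binom.pmf(val, 3, pa) * PC)) / denom
        return out


class TrueExposureModelB(_TrueExposureBase):
    conditions_on_A = True

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        pa, pb, pc = self._binom_weights(data)
        A = np.broadcast_to(np.asarray(data.A if a is None else a), (data.n,))
        PA = binom.pmf(A[None, :], 3, pa)
        PC = binom.pmf(data.C["C"].to_numpy()[None, :], 3, pc)
        base = PA * PC
        denom = self.wu @ base
        out = np.empty((data.n, len(self.support)))
        for j, val in enumerate(self.support):
            out[:, j] = (self.wu @ (binom.pmf(val, 3, pb) * base)) / denom
        return out


def true_nuisances(study: int, n_nodes: int = 64):
    """NuisanceSet holding the exact data-generating nuisance functions."""
    from .nuisance import NuisanceSet

    return NuisanceSet(
        outcome=TrueOutcomeModel(study),
        expA=TrueExposureModelA(study, n_nodes),
        expB=TrueExposureModelB(study, n_nodes),
        crossfit_folds=1,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo counterparts (independent brute-force oracles)
# ---------------------------------------------------------------------------


def _simulate_counterfactual(study: int, n_draws: int, seed):
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n_draws)
    if study == 1:
        cov = {"L": rng.binomial(1, 0.5, size=n_draws)}
        Z = cov["L"].astype(float)
    else:
        cov = {
            "L1": rng.binomial(1, 0.5, size=n_draws),
            "L2": rng.uniform(0.0, 2.0, size=n_draws),
        }
        Z = cov["L2"]
    pa, pb, pc = _exposure_probs(study, cov, u)
    A = rng.binomial(3, pa)
    B = rng.binomial(3, pb)
    C = rng.binomial(3, pc)
    bd = np.minimum(A + B, CAP_X)
    m_int = _m_true(study, 0, bd, C, cov)
    return rng, Z, m_int


def mc_true_mu(study: int, n_draws: int = 10_000_000, seed=0) -> tuple[float, float]:
    """Brute-force simulated-counterfactual mean of Y_g: (estimate, MC SE).

    Draws the full process including the latent U, applies the substitution
    to the natural exposures, draws Y_g from the true outcome law, and
    averages.
    """
    _check_study(study)
    rng, _, m_int = _simulate_counterfactual(study, n_draws, seed)
    yg = rng.binomial(1, m_int)
    p = float(np.mean(yg))
    return p, float(np.sqrt(p * (1.0 - p) / n_draws))


def mc_least_false(study: int, n_draws: int = 10_000_000, seed=0):
    """Monte-Carlo least-false projection: (theta, per-component MC SE).

    Simulates the natural covariates/exposures, evaluates the true outcome
    regression at the intervened exposures, and solves the empirical
    projection score. The MC standard error comes from the M-estimation
    sandwich of that score.
    """
    _check_study(study)
    _, Z, m_int = _simulate_counterfactual(study, n_draws, seed)
    S = np.column_stack([np.ones_like(Z), Z])
    theta, _, _ = solve_weighted_logistic_score(S, m_int)
    g = expit(S @ theta)
    C = (S * (g * (1.0 - g))[:, None]).T @ S / n_draws
    Cinv = np.linalg.inv(C)
    phi = m_int - g
    meat = (S * (phi**2)[:, None]).T @ S / n_draws
    cov = Cinv @ meat @ Cinv.T / n_draws
    return theta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# replication harness
# ---------------------------------------------------------------------------

SCALAR_ESTIMATORS = ("ore", "ipw", "tmle")
MSM_ESTIMATORS = ("msm_ore", "msm_ipw", "msm_tmle")
ALL_ESTIMATORS = SCALAR_ESTIMATORS + MSM_ESTIMATORS


@dataclass
class SimulationResult:
    """Per-replicate estimates plus bias/SE/MSE/coverage aggregates."""

    study: int
    n: int
    reps: int
    scenario: str
    seed: int
    replicates: pd.DataFrame  # rep, estimator, parameter, estimate, se, ci_lo, ci_hi
    truth: dict  # parameter -> true (or least-false) value
    n_failed: int = 0
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Aggregate bias, empirical SE, MSE and 95% CI coverage.

        Refuses to aggregate when more than 1% of replicates failed.
        """
        if self.n_failed > 0.01 * self.reps:
            raise RuntimeError(
                f"{self.n_failed}/{self.reps} replicates failed; aggregates suppressed"
            )
        rows = []
        for (estimator, parameter), grp in self.replicates.groupby(
            ["estimator", "parameter"], sort=False
        ):
            truth = self.truth[parameter]
            est = grp["estimate"].to_numpy()
            bias = float(np.mean(est) - truth)
            se = float(np.std(est, ddof=1))
            mse = float(np.mean((est - truth) ** 2))
            cover = float(np.mean((grp["ci_lo"] <= truth) & (truth <= grp["ci_hi"])))
            rows.append(
                {
                    "estimator": estimator,
                    "parameter": parameter,
                    "truth": truth,
                    "bias": bias,
                    "se": se,
                    "mse": mse,
                    "coverage": cover,
                    "reps": len(grp),
                    "n": self.n,
                    "scenario": self.scenario,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _one_replicate(study, n, scenario, estimators, rep_seed, crossfit, msm_formula):
    data = _generate(study, n, rep_seed)
    spec = InterventionSpec(x=CAP_X)
    specs = scenario_specs(study, scenario)
    fit_seed = int(np.random.SeedSequence(rep_seed).generate_state(1)[0] % (2**31))
    nuis = crossfit_nuisances(
        data, specs["outcome"], specs["expA"], specs["expB"], K=crossfit, seed=fit_seed
    )
    need_weights = any(e in estimators for e in ("ipw", "tmle", "msm_ipw", "msm_tmle"))
    weights = substitution_weights(data, nuis, spec) if need_weights else None
    msm = MSMSpec(msm_formula)
    rows = []

    def add_scalar(name, est):
        rows.append(
            {
                "estimator": name,
                "parameter": "mu",
                "estimate": est.mu_g,
                "se": est.se_mu,
                "ci_lo": est.ci_mu[0],
                "ci_hi": est.ci_mu[1],
            }
        )

    def add_msm(name, est):
        ci = est.ci()
        for j in range(len(est.theta)):
            rows.append(
                {
                    "estimator": name,
                    "parameter": f"theta{j}",
                    "estimate": float(est.theta[j]),
                    "se": float(est.se[j]),
                    "ci_lo": float(ci[j, 0]),
                    "ci_hi": float(ci[j, 1]),
                }
            )

    if "ore" in estimators:
        add_scalar("ore", ore(data, nuis.outcome, spec))
    if "ipw" in estimators:
        add_scalar("ipw", ipw(data, nuis.expA, nuis.expB, spec, weights=weights))
    if "tmle" in estimators:
        add_scalar("tmle", tmle(data, nuis, spec, weights=weights))
    if "msm_ore" in estimators:
        add_msm("msm_ore", msm_ore(data, nuis.outcome, msm, spec))
    if "msm_ipw" in estimators:
        add_msm("msm_ipw", msm_ipw(data, nuis.expA, nuis.expB, msm, spec, weights=weights))
    if "msm_tmle" in estimators:
        add_msm("msm_tmle", msm_tmle(data, nuis, msm, spec, weights=weights))
    return rows


def run_replications(
    study: int,
    n: int,
    reps: int,
    scenario: str = "correct",
    estimators=ALL_ESTIMATORS,
    seed: int = 0,
    crossfit: int = 1,
    msm_formula: str | None = None,
) -> SimulationResult:
    """Monte-Carlo evaluation of the estimators against the oracles.

    Replicate r uses the counter-based seed sequence [seed, r], so runs are
    bitwise reproducible and individual replicates re-runnable. The scalar
    target is the true mu_g; the MSM target is the least-false parameter.
    Replicate-level failures are recorded and excluded (aggregation refuses
    if they exceed 1%).
    """
    _check_study(study)
    if reps < 2:
        raise ValueError("reps must be >= 2")
    unknown = set(estimators) - set(ALL_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators {sorted(unknown)}")
    msm_formula = msm_formula or msm_design(study)

    truth = {}
    if any(e in SCALAR_ESTIMATORS for e in estimators):
        truth["mu"], _ = true_mu_oracle(study)
    if any(e in MSM_ESTIMATORS for e in estimators):
        theta_star, _ = least_false_oracle(study)
        truth.update({f"theta{j}": float(v) for j, v in enumerate(theta_star)})

    all_rows, failures = [], []
    for rep in range(reps):
        try:
            rows = _one_replicate(
                study, n, scenario, estimators, [seed, rep], crossfit, msm_formula
            )
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            failures.append((rep, repr(exc)))
            continue
        for row in rows:
            row["rep"] = rep
        all_rows.extend(rows)
    replicates = pd.DataFrame(
        all_rows, columns=["rep", "estimator", "parameter", "estimate", "se", "ci_lo", "ci_hi"]
    )
    return SimulationResult(
        study=study,
        n=n,
        reps=reps,
        scenario=scenario,
        seed=seed,
        replicates=replicates,
        truth=truth,
        n_failed=len(failures),
        failures=failures,
    )
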