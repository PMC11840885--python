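import numpy as np
import pandas as pd
import pytest

from dietsub import (
    InterventionSpec,
    contrast,
    crossfit_nuisances,
    eif_values,
    fit_outcome_model,
    ipw,
    ore,
    substitution_weights,
    tmle,
    validate_dataset,
)
from dietsub import simulation as sim
from dietsub.nuisance import NuisanceSet

from conftest import ConstantOutcome


class _FrozenOutcome:
    """Wraps precomputed predictions (used to probe the fluctuation)."""

    def __init__(self, m_obs, m_int):
        self.m_obs = m_obs
        self.m_int = m_int
        self.descriptor = {"backend": "frozen"}

    def predict(self, data, a=None, b=None):
        return self.m_obs if a is None else self.m_int


class TestORE:
    def test_constant_model_returns_ybar(self, study1_small, spec3):
        est = ore(study1_small, ConstantOutcome(study1_small.Y.mean()), spec3)
        assert est.mu_g == pytest.approx(study1_small.Y.mean(), abs=1e-12)

    def test_noop_intervention_returns_ybar(self):
        """With A identically 0 and x = max support, the intervention is a
        no-op and the intercept-containing logistic plug-in equals ybar."""
        rng = np.random.default_rng(5)
        n = 800
        table = pd.DataFrame(
            {
                "L": rng.binomial(1, 0.5, n),
                "A": np.zeros(n, dtype=int),
                "B": rng.integers(0, 4, n),
                "C": rng.integers(0, 4, n),
                "Y": rng.binomial(1, 0.4, n),
            }
        )
        data = validate_dataset(table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"})
        model = fit_outcome_model(data, "B + C + L")
        est = ore(data, model, InterventionSpec(x=3))
        assert est.mu_g == pytest.approx(data.Y.mean(), abs=1e-8)
        est = contrast(data, est)
        assert est.delta == pytest.approx(0.0, abs=1e-8)


class TestIPW:
    def test_toy_weighted_mean(self):
        from types import SimpleNamespace

        from conftest import FixedExposureA, FixedExposureB

        table = pd.DataFrame(
            {
                "L": [0, 0, 0, 0],
                "A": [0, 0, 1, 0],
                "B": [1, 0, 1, 1],
                "C": [0, 0, 0, 0],
                "Y": [1, 0, 1, 0],
            }
        )
        data = validate_dataset(
            table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"},
            support_A=[0, 1], support_B=[0, 1],
        )
        expA = FixedExposureA([0.5, 0.5], [0, 1])
        expB = FixedExposureB({0: [0.5, 0.5], 1: [0.5, 0.5]}, [0, 1])
        est = ipw(data, expA, expB, InterventionSpec(x=2))
        # hand computation: qtilde = (0.25, 0.5, 0.25); records with A=0:
        # (B=1) W = 0.5/0.25 = 2 (twice), (B=0) W = 0.25/0.25 = 1
        # mu = (2*1 + 1*0 + 2*0) / (2 + 1 + 2) = 0.4
        assert est.mu_g == pytest.approx(0.4, abs=1e-12)

    def test_all_weights_zero_raises(self, spec3):
        table = pd.DataFrame(
            {"L": [0, 0], "A": [1, 2], "B": [0, 1], "C": [0, 0], "Y": [0, 1]}
        )
        data = validate_dataset(
            table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"},
            support_A=[0, 1, 2, 3], support_B=[0, 1, 2, 3],
        )
        nuis = sim.true_nuisances(1)
        with pytest.raises(ValueError, match="no records with A=0"):
            ipw(data, nuis.expA, nuis.expB, spec3)


class TestEIF:
    def test_indicator_kills_residual_for_a_nonzero(self, study1_small, study1_nuisances, spec3):
        mu = 0.5
        vals = eif_values(study1_small, study1_nuisances, spec3, mu)
        m_int = study1_nuisances.outcome.predict(
            study1_small, a=0, b=np.minimum(study1_small.A + study1_small.B, 3)
        )
        nz = study1_small.A != 0
        assert np.allclose(vals[nz], m_int[nz] - mu, atol=1e-12)

    def test_mean_zero_at_truth(self, spec3):
        data = sim.generate_study1(100_000, 31)
        nuis = sim.true_nuisances(1)
        mu, _ = sim.true_mu_oracle(1)
        vals = eif_values(data, nuis, spec3, mu)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(data.n)


class TestTMLE:
    def test_solves_eif_equation(self, study1_small, study1_nuisances, spec3):
        est = tmle(study1_small, study1_nuisances, spec3)
        assert abs(np.mean(est.if_values)) < 1e-8
        assert est.se_mu == pytest.approx(
            np.std(est.if_values, ddof=1) / np.sqrt(study1_small.n), rel=1e-12
        )

    def test_zero_epsilon_reduces_to_ore(self, study1_small, study1_nuisances, spec3):
        """Re-targeting an already-targeted fit gives epsilon = 0 and the
        plug-in equals the ORE on that fit."""
        first = tmle(study1_small, study1_nuisances, spec3)
        w = substitution_weights(study1_small, study1_nuisances, spec3)
        from scipy.special import expit, logit

        m_obs = expit(logit(study1_nuisances.outcome.predict(study1_small)) + first.epsilon)
        bd = np.minimum(study1_small.A + study1_small.B, 3)
        m_int = expit(
            logit(study1_nuisances.outcome.predict(study1_small, a=0, b=bd)) + first.epsilon
        )
        frozen = NuisanceSet(
            outcome=_FrozenOutcome(m_obs, m_int),
            expA=study1_nuisances.expA,
            expB=study1_nuisances.expB,
        )
        second = tmle(study1_small, frozen, spec3, weights=w)
        assert abs(second.epsilon) < 1e-10
        assert second.mu_g == pytest.approx(
            ore(study1_small, frozen.outcome, spec3).mu_g, abs=1e-10
        )
        assert second.mu_g == pytest.approx(first.mu_g, abs=1e-10)


class TestAgreementWithOracle:
    def test_all_estimators_agree_under_true_nuisances(self, spec3):
        data = sim.generate_study1(100_000, 41)
        nuis = sim.true_nuisances(1)
        mu, ey = sim.true_mu_oracle(1)
        w = substitution_weights(data, nuis, spec3)
        ests = [
            ore(data, nuis.outcome, spec3),
            ipw(data, nuis.expA, nuis.expB, spec3, weights=w),
            tmle(data, nuis, spec3, weights=w),
        ]
        for est in ests:
            assert abs(est.mu_g - mu) < 3 * est.se_mu
        est = contrast(data, ests[2])
        assert abs(est.delta - (ey - mu)) < 3 * est.se_delta


class TestDoubleRobustness:
    @pytest.mark.parametrize(
        "scenario, broken",
        [("mis_outcome", "ore"), ("mis_exposure", "ipw")],
    )
    def test_tmle_beats_broken_singly_robust(self, scenario, broken):
        """Union-model consistency: TMLE stays nearly unbiased when one
        nuisance block is misspecified; the matching singly-robust
        estimator does not."""
        res = sim.run_replications(
            1, 2000, 40, scenario, estimators=("ore", "ipw", "tmle"), seed=3
        )
        s = res.summary().set_index(["estimator", "parameter"])
        bias_tmle = abs(s.loc[("tmle", "mu"), "bias"])
        bias_broken = abs(s.loc[(broken, "mu"), "bias"])
        assert bias_tmle < bias_broken
        assert bias_tmle < 0.03
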