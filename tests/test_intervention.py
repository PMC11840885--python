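import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietsub import (
    InterventionSpec,
    apply_intervention,
    q_pointmass,
    qtilde_pmf,
    substitute_dose,
    substitution_weights,
    validate_dataset,
)
from dietsub import simulation as sim
from dietsub.intervention import qtilde_records

from conftest import FixedExposureA, FixedExposureB


class TestSubstituteDose:
    @pytest.mark.parametrize(
        "a, b, x, expected",
        [(2, 1, 7, 3), (0, 5, 7, 5), (4, 6, 7, 7), (3, 3, 3, 3), (0, 0, 1, 0)],
    )
    def test_examples(self, a, b, x, expected):
        assert substitute_dose(a, b, x) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            substitute_dose(-1, 0, 3)
        with pytest.raises(ValueError):
            substitute_dose(0, 0, 0)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(1, 15))
    def test_kernel_is_indicator_of_dose(self, a, b, x):
        d = substitute_dose(a, b, x)
        assert d <= x
        for bd in range(x + 1):
            assert q_pointmass(bd, a, b, x) == int(bd == d)
        assert sum(q_pointmass(bd, a, b, x) for bd in range(x + 1)) == 1


class TestApplyIntervention:
    def test_worked_plan(self, spec3):
        table = pd.DataFrame({"L": [0], "A": [2], "B": [1], "C": [4], "Y": [0]})
        data = validate_dataset(table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"})
        out = apply_intervention(data, InterventionSpec(x=7))
        assert out.loc[0, "A_dagger"] == 0
        assert out.loc[0, "B_dagger"] == 3
        assert out.loc[0, "C_dagger"] == 4

    def test_noop_when_a_zero_and_under_cap(self, spec3):
        data = sim.generate_study1(500, 9)
        idx = np.flatnonzero(data.A == 0)
        out = apply_intervention(data, spec3)
        assert np.array_equal(out["B_dagger"].to_numpy()[idx], data.B[idx])
        assert (out["B_dagger"] <= 3).all()
        assert (out["A_dagger"] == 0).all()


def _random_pmf(rng, size):
    p = rng.dirichlet(np.ones(size))
    return p


class TestQtilde:
    def test_uniform_example(self):
        # pA uniform on {0,1}, pB(.|a) uniform on {0,1}, x=2
        pA = [0.5, 0.5]
        pB = [[0.5, 0.5], [0.5, 0.5]]
        vals = [qtilde_pmf(bd, pA, pB, 2) for bd in range(3)]
        assert vals == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)

    def test_cap_term_example(self):
        # pA point mass at 1, pB(.|1) uniform on {0,1}, x=1
        pA = [0.0, 1.0]
        pB = [[0.5, 0.5], [0.5, 0.5]]
        assert qtilde_pmf(1, pA, pB, 1) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="not a normalized pmf"):
            qtilde_pmf(0, [0.5, 0.6], [[1.0, 0.0], [1.0, 0.0]], 1)

    def test_matches_enumeration_and_normalizes(self):
        """q~ equals brute-force enumeration of (a, b) mapped through d."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            nA = rng.integers(1, 11)
            nB = rng.integers(1, 11)
            sA = np.sort(rng.choice(20, size=nA, replace=False))
            sB = np.sort(rng.choice(20, size=nB, replace=False))
            x = int(rng.integers(1, 16))
            pA = _random_pmf(rng, nA)
            pB = np.stack([_random_pmf(rng, nB) for _ in range(nA)])
            # independent oracle: exhaustive enumeration
            oracle = np.zeros(x + 1)
            for i, a in enumerate(sA):
                for j, b in enumerate(sB):
                    oracle[substitute_dose(int(a), int(b), x)] += pA[i] * pB[i, j]
            vals = np.array(
                [qtilde_pmf(bd, pA, pB, x, support_A=sA, support_B=sB) for bd in range(x + 1)]
            )
            assert np.max(np.abs(vals - oracle)) < 1e-12
            assert abs(vals.sum() - 1.0) < 1e-10

    def test_vectorized_matches_pointwise(self, study1_small, study1_nuisances):
        QT = qtilde_records(study1_small, study1_nuisances.expA, study1_nuisances.expB, 3)
        assert QT.shape == (study1_small.n, 4)
        assert np.allclose(QT.sum(axis=1), 1.0, atol=1e-10)
        PA = study1_nuisances.expA.pmf_matrix(study1_small)
        i = 17
        pB = np.stack(
            [
                study1_nuisances.expB.pmf_matrix(study1_small, a)[i]
                for a in study1_nuisances.expA.support
            ]
        )
        for bd in range(4):
            assert QT[i, bd] == pytest.approx(
                qtilde_pmf(bd, PA[i], pB, 3, support_A=np.arange(4), support_B=np.arange(4)),
                abs=1e-12,
            )


class TestWeights:
    def _toy(self):
        # single stratum; observed record (A=0, B=1) among fillers
        table = pd.DataFrame(
            {
                "L": [0, 0, 0],
                "A": [0, 1, 0],
                "B": [1, 1, 0],
                "C": [0, 0, 0],
                "Y": [1, 0, 0],
            }
        )
        data = validate_dataset(
            table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"},
            support_A=[0, 1], support_B=[0, 1],
        )
        expA = FixedExposureA([0.5, 0.5], [0, 1])
        expB = FixedExposureB({0: [0.5, 0.5], 1: [0.5, 0.5]}, [0, 1])
        return data, expA, expB

    def test_hand_computed_weight(self):
        from types import SimpleNamespace

        data, expA, expB = self._toy()
        wv = substitution_weights(data, SimpleNamespace(expA=expA, expB=expB), InterventionSpec(x=2))
        # record 0: A=0, B=1 -> W = qtilde(1)/(pA(0) pB(1|0)) = 0.5/0.25 = 2
        assert wv.W[0] == pytest.approx(2.0, abs=1e-12)
        # record 1 has A != 0 -> exactly zero
        assert wv.W[1] == 0.0
        assert wv.n_truncated == 0

    def test_mean_weight_one_with_true_pmfs(self, spec3):
        data = sim.generate_study1(100_000, 13)
        nuis = sim.true_nuisances(1)
        wv = substitution_weights(data, nuis, spec3)
        se = np.std(wv.W, ddof=1) / np.sqrt(data.n)
        assert abs(np.mean(wv.W) - 1.0) < 3 * se
        # E[W Y] identifies mu_g
        mu, _ = sim.true_mu_oracle(1)
        wy = wv.W * data.Y
        se_wy = np.std(wy, ddof=1) / np.sqrt(data.n)
        assert abs(np.mean(wy) - mu) < 3 * se_wy

    def test_cap_above_support_rejected(self, study1_small):
        spec = InterventionSpec(x=5)
        with pytest.raises(ValueError, match="exceeds max support"):
            spec.validate_against(study1_small)
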