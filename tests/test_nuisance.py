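import numpy as np
import pandas as pd
import pytest

from dietsub import crossfit_nuisances, fit_exposure_models, fit_outcome_model, validate_dataset
from dietsub import simulation as sim


class TestOutcomeModel:
    def test_correct_specification_recovers_coefficients(self):
        """Logistic fit of the true outcome form at large n recovers
        (-1, -1, +1, +1, -2) for (intercept, A, B, C, L)."""
        data = sim.generate_study1(100_000, 21)
        model = fit_outcome_model(data, "A + B + C + L")
        params = model._result.params
        expected = {"Intercept": -1.0, "A": -1.0, "B": 1.0, "C": 1.0, "L": -2.0}
        for name, target in expected.items():
            assert params[name] == pytest.approx(target, abs=0.08)

    def test_predictions_converge_on_exposure_grid(self):
        data = sim.generate_study1(400_000, 22)
        model = fit_outcome_model(data, "A + B + C + L")
        grid = pd.DataFrame(
            [(a, b, c, l, 0) for a in range(4) for b in range(4) for c in range(4) for l in (0, 1)],
            columns=["A", "B", "C", "L", "Y"],
        )
        gd = validate_dataset(grid, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"})
        pred = model.predict(gd)
        truth = sim.TrueOutcomeModel(1).predict(gd)
        assert np.max(np.abs(pred - truth)) < 0.01

    def test_misspecified_working_model_fits(self, study1_small):
        model = fit_outcome_model(study1_small, "A + B:L + C:L")
        p = model.predict(study1_small)
        assert np.all((p > 0) & (p < 1))

    def test_constant_only_formula(self, study1_small):
        model = fit_outcome_model(study1_small, "1")
        assert np.allclose(model.predict(study1_small), study1_small.Y.mean(), atol=1e-8)

    def test_mean_residual_zero_with_intercept(self, study1_small, study1_nuisances):
        resid = study1_small.Y - study1_nuisances.outcome.predict(study1_small)
        assert abs(resid.mean()) < 1e-8

    def test_gbt_backend_deterministic_given_seed(self, study1_small):
        m1 = fit_outcome_model(study1_small, {"backend": "gbt", "seed": 5})
        m2 = fit_outcome_model(study1_small, {"backend": "gbt", "seed": 5})
        assert np.array_equal(m1.predict(study1_small), m2.predict(study1_small))


class TestExposureModels:
    @pytest.mark.parametrize("backend", ["saturated", "multinomial", "multinomial_spline"])
    def test_pmfs_normalize(self, study1_small, backend):
        specB = {"backend": backend}
        if backend == "multinomial":
            specB["formula"] = "A + C + L"
        specA = dict(specB)
        if backend == "multinomial":
            specA["formula"] = "C + L"
        expA, expB = fit_exposure_models(study1_small, specA, specB)
        PA = expA.pmf_matrix(study1_small)
        assert np.allclose(PA.sum(axis=1), 1.0, atol=1e-8)
        for a in range(4):
            PB = expB.pmf_matrix(study1_small, a)
            assert np.allclose(PB.sum(axis=1), 1.0, atol=1e-8)

    def test_binomial_backend_cdf_monotone(self, study1_small):
        _, expB = fit_exposure_models(
            study1_small, {"backend": "binomial", "formula": "C"},
            {"backend": "binomial", "formula": "A + C"},
        )
        for a in range(4):
            F = expB.cdf_matrix(study1_small, a)
            assert np.all(np.diff(F, axis=1) >= -1e-12)
            assert np.allclose(F[:, -1], 1.0, atol=1e-8)

    def test_degenerate_constant_exposure(self):
        table = pd.DataFrame(
            {"L": [0, 1, 0, 1], "A": [0, 1, 2, 0], "B": [2, 2, 2, 2], "C": [0, 0, 1, 1],
             "Y": [0, 1, 0, 1]}
        )
        data = validate_dataset(table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"})
        _, expB = fit_exposure_models(
            data, {"backend": "saturated"}, {"backend": "multinomial"}
        )
        P = expB.pmf_matrix(data, 0)
        assert P.shape == (4, 1)  # observed support is the single level {2}
        assert np.allclose(P, 1.0)  # point mass for every record

    def test_saturated_matches_empirical_frequencies(self, study1_small):
        expA, _ = fit_exposure_models(
            study1_small, {"backend": "saturated"}, {"backend": "saturated"}
        )
        # check one stratum by hand
        mask = (study1_small.C["C"].to_numpy() == 1) & (
            study1_small.L["L"].to_numpy() == 0
        )
        emp = np.bincount(study1_small.A[mask], minlength=4) / mask.sum()
        row = expA.pmf_matrix(study1_small)[np.flatnonzero(mask)[0]]
        assert np.allclose(row, emp, atol=1e-12)


class TestCrossFitting:
    def test_same_folds_on_rerun(self, study1_small):
        n1 = crossfit_nuisances(
            study1_small, "A + B + C + L", {"backend": "saturated"},
            {"backend": "saturated"}, K=2, seed=99,
        )
        n2 = crossfit_nuisances(
            study1_small, "A + B + C + L", {"backend": "saturated"},
            {"backend": "saturated"}, K=2, seed=99,
        )
        assert np.array_equal(n1.fold_assignment, n2.fold_assignment)
        assert np.array_equal(
            n1.outcome.predict(study1_small), n2.outcome.predict(study1_small)
        )

    def test_k1_reduces_to_direct_fit(self, study1_small):
        direct = fit_outcome_model(study1_small, "A + B + C + L")
        nuis = crossfit_nuisances(
            study1_small, "A + B + C + L", {"backend": "saturated"},
            {"backend": "saturated"}, K=1,
        )
        assert np.allclose(
            direct.predict(study1_small), nuis.outcome.predict(study1_small), atol=1e-12
        )

    def test_out_of_fold_pmfs_normalized(self):
        data = sim.generate_study2(1500, 8)
        nuis = crossfit_nuisances(
            data, "A + B + C + L1 + L2", {"backend": "multinomial_spline"},
            {"backend": "multinomial_spline"}, K=5, seed=1,
        )
        PA = nuis.expA.pmf_matrix(data)
        assert np.allclose(PA.sum(axis=1), 1.0, atol=1e-8)
        PB = nuis.expB.pmf_matrix(data, 2)
        assert np.allclose(PB.sum(axis=1), 1.0, atol=1e-8)
        # out-of-fold contract: each record predicted by a model not trained on it
        assert nuis.crossfit_folds == 5
        assert len(np.unique(nuis.fold_assignment)) == 5

    def test_invalid_k(self, toy_dataset):
        with pytest.raises(ValueError, match="1 <= K <= n"):
            crossfit_nuisances(toy_dataset, "1", {"backend": "saturated"},
                               {"backend": "saturated"}, K=10)
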