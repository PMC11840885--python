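"""Nuisance function estimation.

Three nuisance functions drive every estimator in the package:

* the outcome regression  m(A, B, C, L) = E(Y | A, B, C, L),
* the exposure pmf        p(A = a | C, L) over the finite support of A,
* the exposure pmf        p(B = b | A, C, L) over the finite support of B.

Each has parametric back-ends (logistic / Binomial-logistic /
multinomial-logistic via formulas) and flexible back-ends (gradient-boosted
trees for the outcome; multinomial logistic regression on a spline basis
expansion of continuous covariates for the exposures), plus a saturated
empirical back-end for fully discrete conditioning sets. Optional K-fold
cross-fitting gives out-of-fold predictions for every record, supporting
valid inference with flexible learners.

Learner specifications are dictionaries with a ``"backend"`` key, e.g.
``{"backend": "logistic", "formula": "A + B + C + L"}``; a bare string is
shorthand for the default parametric back-end with that formula. Formulas
use Wilkinson notation and refer to the exposures as ``A`` and ``B``, the
outcome as ``Y`` and covariates by their column names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import binom

from .data_model import ObservedDataset

__all__ = [
    "NuisanceSet",
    "fit_outcome_model",
    "fit_exposure_models",
    "crossfit_nuisances",
]

PRED_BOUND = 1e-6  # outcome predictions bounded away from {0, 1} before logit


def _normalize_spec(spec, default_backend: str) -> dict:
    if isinstance(spec, str):
        return {"backend": default_backend, "formula": spec}
    if isinstance(spec, Mapping):
        d = dict(spec)
        d.setdefault("backend", default_backend)
        return d
    raise TypeError(f"learner spec must be a formula string or mapping, got {spec!r}")


def _frame(data: ObservedDataset) -> pd.DataFrame:
    return data.to_frame()


def _override(df: pd.DataFrame, a=None, b=None) -> pd.DataFrame:
    if a is None and b is None:
        return df
    df = df.copy()
    if a is not None:
        df["A"] = np.broadcast_to(np.asarray(a), (len(df),)).astype(np.int64)
    if b is not None:
        df["B"] = np.broadcast_to(np.asarray(b), (len(df),)).astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# outcome regression back-ends
# ---------------------------------------------------------------------------


class FormulaLogisticOutcome:
    """Logistic outcome regression specified by a Wilkinson formula."""

    def __init__(self, formula: str):
        self.formula = formula
        self.descriptor = {"backend": "logistic", "formula": formula}

    def fit(self, data: ObservedDataset) -> "FormulaLogisticOutcome":
        df = _frame(data)
        y, X = patsy.dmatrices(f"Y ~ {self.formula}", df, return_type="dataframe")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if not res.converged:
            raise RuntimeError(
                f"outcome logistic regression did not converge: {res.mle_retvals!r}"
            )
        self._design_info = X.design_info
        self._result = res
        return self

    def predict(self, data: ObservedDataset, a=None, b=None) -> np.ndarray:
        df = _override(_frame(data), a, b)
        (X,) = patsy.build_design_matrices([self._design_info], df, return_type="dataframe")
        p = np.asarray(self._result.predict(X))
        return np.clip(p, PRED_BOUND, 1.0 - PRED_BOUND)


class GBTOutcome:
    """Gradient-boosted tree outcome regression with cross-validated depth."""

    def __init__(self, max_depths=(2, 3), max_iter: int = 200, seed: int = 0):
        self.max_depths = tuple(max_depths)
        self.max_iter = max_iter
        self.seed = seed
        self.descriptor = {
            "backend": "gbt",
            "max_depths": list(self.max_depths),
            "max_iter": max_iter,
            "seed": seed,
        }

    @staticmethod
    def _features(data: ObservedDataset, a=None, b=None) -> np.ndarray:
        A = np.broadcast_to(np.asarray(data.A if a is None else a), (data.n,)).astype(float)
        B = np.broadcast_to(np.asarray(data.B if b is None else b), (data.n,)).astype(float)
        return np.column_stack(
            [A, B, data.C.to_numpy(dtype=float), data.L.to_numpy(dtype=float)]
        )

    def fit(self, data: ObservedDataset) -> "GBTOutcome":
        from sklearn.ensemble import HistGradientBoostingClassifier
        from sklearn.model_selection import GridSearchCV

        X = self._features(data)
        base = HistGradientBoostingClassifier(
            max_iter=self.max_iter, random_state=self.seed, early_stopping=False
        )
        if len(self.max_depths) > 1:
            gs = GridSearchCV(
                base,
                {"max_depth": list(self.max_depths)},
                cv=2,
                scoring="neg_log_loss",
            )
            gs.fit(X, data.Y)
            self._model = gs.best_estimator_
        else:
            self._model = base.set_params(max_depth=self.max_depths[0]).fit(X, data.Y)
        return self

    def predict(self, data: ObservedDataset, a=None, b=None) -> np.ndarray:
        p = self._model.predict_proba(self._features(data, a, b))[:, 1]
        return np.clip(p, PRED_BOUND, 1.0 - PRED_BOUND)


# ---------------------------------------------------------------------------
# exposure pmf back-ends
# ---------------------------------------------------------------------------


class _ExposureBase:
    """Common pmf/cdf plumbing: subclasses provide pmf_matrix."""

    support: np.ndarray
    conditions_on_A: bool = False

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def cdf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        """Cumulative pmf over the ordered support, columns aligned to it."""
        return np.cumsum(self.pmf_matrix(data, a), axis=1)


class SaturatedExposureModel(_ExposureBase):
    """Empirical conditional pmf over exact strata of discrete conditioners.

    The nonparametric MLE for fully discrete conditioning sets: within each
    exact stratum of the conditioning columns, the pmf is the observed
    frequency over the support. Strata never seen in training fall back to
    the uniform pmf (they can only be reached with zero probability weight
    when the companion exposure model is fitted on the same data).
    """

    def __init__(self, role: str):
        if role not in ("A", "B"):
            raise ValueError("role must be 'A' or 'B'")
        self.role = role
        self.conditions_on_A = role == "B"
        self.descriptor = {"backend": "saturated", "role": role}

    def _keys(self, data: ObservedDataset, a=None) -> pd.DataFrame:
        cols = {}
        if self.conditions_on_A:
            cols["A"] = np.broadcast_to(np.asarray(data.A if a is None else a), (data.n,))
        for c in data.C.columns:
            cols[c] = data.C[c].to_numpy()
        for c in data.L.columns:
            cols[c] = data.L[c].to_numpy()
        return pd.DataFrame(cols)

    def fit(self, data: ObservedDataset) -> "SaturatedExposureModel":
        self.support = np.asarray(
            data.support_A if self.role == "A" else data.support_B, dtype=int
        )
        target = data.A if self.role == "A" else data.B
        keys = self._keys(data)
        keys = keys.assign(_target=target)
        tab = (
            keys.groupby(list(keys.columns[:-1]) + ["_target"], sort=False)
            .size()
            .unstack("_target", fill_value=0)
        )
        tab = tab.reindex(columns=self.support, fill_value=0)
        probs = tab.to_numpy(dtype=float)
        probs /= probs.sum(axis=1, keepdims=True)
        self._table = pd.DataFrame(
            probs, index=tab.index, columns=[f"_p{v}" for v in self.support]
        ).reset_index()
        self._key_cols = [c for c in self._table.columns if not c.startswith("_p")]
        return self

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        keys = self._keys(data, a)
        merged = keys.merge(self._table, how="left", on=self._key_cols)
        P = merged[[f"_p{v}" for v in self.support]].to_numpy(dtype=float)
        unseen = np.isnan(P[:, 0])
        if unseen.any():
            P[unseen] = 1.0 / len(self.support)
        return P


class BinomialExposureModel(_ExposureBase):
    """Binomial-logistic pmf: count ~ Binomial(max support, expit(X beta))."""

    def __init__(self, role: str, formula: str):
        self.role = role
        self.formula = formula
        self.conditions_on_A = role == "B"
        self.descriptor = {"backend": "binomial", "role": role, "formula": formula}

    def fit(self, data: ObservedDataset) -> "BinomialExposureModel":
        self.support = np.asarray(
            data.support_A if self.role == "A" else data.support_B, dtype=int
        )
        self.size = int(self.support.max())
        target = np.asarray(data.A if self.role == "A" else data.B)
        df = _frame(data)
        X = patsy.dmatrix(self.formula, df, return_type="dataframe")
        endog = np.column_stack([target, self.size - target])
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        if not res.converged:
            raise RuntimeError("Binomial-logistic exposure model did not converge")
        self._design_info = X.design_info
        self._result = res
        return self

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        df = _override(_frame(data), a=a if self.conditions_on_A else None)
        (X,) = patsy.build_design_matrices([self._design_info], df, return_type="dataframe")
        p = np.asarray(self._result.predict(X))
        return binom.pmf(self.support[None, :], self.size, p[:, None])


class MultinomialExposureModel(_ExposureBase):
    """Multinomial-logistic pmf over the support, optionally on a spline basis.

    With ``spline=True``, continuous conditioning covariates are expanded in
    a cubic B-spline basis before the multinomial fit (the package's default
    flexible exposure learner). Support values absent from the training data
    receive probability zero.
    """

    def __init__(self, role: str, formula: str | None = None, spline: bool = False,
                 n_knots: int = 5, C_reg: float = 1e6):
        self.role = role
        self.formula = formula
        self.spline = spline
        self.n_knots = n_knots
        self.C_reg = C_reg
        self.conditions_on_A = role == "B"
        self.descriptor = {
            "backend": "multinomial_spline" if spline else "multinomial",
            "role": role,
            "formula": formula,
            "n_knots": n_knots,
        }

    def _design(self, data: ObservedDataset, a=None, fit: bool = False) -> np.ndarray:
        df = _override(_frame(data), a=a if self.conditions_on_A else None)
        if self.formula is not None:
            if fit:
                X = patsy.dmatrix(f"0 + {self.formula}", df, return_type="dataframe")
                self._design_info = X.design_info
            else:
                (X,) = patsy.build_design_matrices(
                    [self._design_info], df, return_type="dataframe"
                )
            return np.asarray(X, dtype=float)
        # raw conditioning columns: A (for the B model), C, L
        cols = ([df["A"].to_numpy(float)] if self.conditions_on_A else [])
        cols += [df[c].to_numpy(float) for c in data.C.columns]
        cont, disc = [], []
        for c in data.L.columns:
            v = df[c].to_numpy(float)
            if self.spline and not np.allclose(v, np.rint(v)):
                cont.append(v)
            else:
                disc.append(v)
        X = np.column_stack(cols + disc) if (cols or disc) else np.empty((len(df), 0))
        if cont:
            from sklearn.preprocessing import SplineTransformer

            M = np.column_stack(cont)
            if fit:
                self._spline = SplineTransformer(
                    n_knots=self.n_knots, degree=3, include_bias=False
                ).fit(M)
            X = np.column_stack([X, self._spline.transform(M)])
        return X

    def fit(self, data: ObservedDataset) -> "MultinomialExposureModel":
        from sklearn.linear_model import LogisticRegression

        self.support = np.asarray(
            data.support_A if self.role == "A" else data.support_B, dtype=int
        )
        target = np.asarray(data.A if self.role == "A" else data.B)
        X = self._design(data, fit=True)
        if len(np.unique(target)) == 1:
            self._constant = int(target[0])
            self._model = None
            return self
        self._constant = None
        self._model = LogisticRegression(
            C=self.C_reg, max_iter=2000, solver="lbfgs"
        ).fit(X, target)
        return self

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        out = np.zeros((data.n, len(self.support)))
        if self._model is None:
            out[:, np.flatnonzero(self.support == self._constant)[0]] = 1.0
            return out
        X = self._design(data, a=a)
        proba = self._model.predict_proba(X)
        for j, cls in enumerate(self._model.classes_):
            out[:, np.flatnonzero(self.support == cls)[0]] = proba[:, j]
        return out


# ---------------------------------------------------------------------------
# cross-fitting
# ---------------------------------------------------------------------------


class _CrossFitOutcome:
    """Stitches per-fold outcome models into out-of-fold predictions."""

    def __init__(self, models, fold_of_record: np.ndarray):
        self._models = models
        self._fold = fold_of_record
        self.descriptor = {
            "backend": "crossfit",
            "folds": len(models),
            "inner": models[0].descriptor,
        }

    def predict(self, data: ObservedDataset, a=None, b=None) -> np.ndarray:
        if data.n != len(self._fold):
            raise ValueError("cross-fitted model can only predict on its training dataset")
        out = np.empty(data.n)
        for k, model in enumerate(self._models):
            idx = np.flatnonzero(self._fold == k)
            sub = data.subset(idx)
            a_k = None if a is None else np.broadcast_to(np.asarray(a), (data.n,))[idx]
            b_k = None if b is None else np.broadcast_to(np.asarray(b), (data.n,))[idx]
            out[idx] = model.predict(sub, a=a_k, b=b_k)
        return out


class _CrossFitExposure(_ExposureBase):
    def __init__(self, models, fold_of_record: np.ndarray):
        self._models = models
        self._fold = fold_of_record
        self.support = models[0].support
        self.conditions_on_A = models[0].conditions_on_A
        self.descriptor = {
            "backend": "crossfit",
            "folds": len(models),
            "inner": models[0].descriptor,
        }

    def pmf_matrix(self, data: ObservedDataset, a=None) -> np.ndarray:
        if data.n != len(self._fold):
            raise ValueError("cross-fitted model can only predict on its training dataset")
        out = np.empty((data.n, len(self.support)))
        for k, model in enumerate(self._models):
            idx = np.flatnonzero(self._fold == k)
            sub = data.subset(idx)
            a_k = None if a is None else np.broadcast_to(np.asarray(a), (data.n,))[idx]
            out[idx] = model.pmf_matrix(sub, a=a_k)
        return out


@dataclass
class NuisanceSet:
    """Fitted outcome regression and the two exposure pmf models."""

    outcome: object
    expA: object
    expB: object
    crossfit_folds: int = 1
    fold_assignment: np.ndarray | None = None

    @property
    def descriptors(self) -> dict:
        return {
            "outcome": self.outcome.descriptor,
            "expA": self.expA.descriptor,
            "expB": self.expB.descriptor,
            "crossfit_folds": self.crossfit_folds,
        }


# ---------------------------------------------------------------------------
# public constructors
# ---------------------------------------------------------------------------


def _make_outcome(spec, seed: int = 0):
    spec = _normalize_spec(spec, "logistic")
    backend = spec["backend"]
    if backend == "logistic":
        return FormulaLogisticOutcome(spec["formula"])
    if backend == "gbt":
        return GBTOutcome(
            max_depths=spec.get("max_depths", (2, 3)),
            max_iter=spec.get("max_iter", 200),
            seed=spec.get("seed", seed),
        )
    raise ValueError(f"unknown outcome backend {backend!r}")


def _make_exposure(spec, role: str):
    spec = _normalize_spec(spec, "binomial")
    backend = spec["backend"]
    if backend == "saturated":
        return SaturatedExposureModel(role)
    if backend == "binomial":
        return BinomialExposureModel(role, spec["formula"])
    if backend == "multinomial":
        return MultinomialExposureModel(role, formula=spec.get("formula"))
    if backend == "multinomial_spline":
        return MultinomialExposureModel(
            role, spline=True, n_knots=spec.get("n_knots", 5)
        )
    raise ValueError(f"unknown exposure backend {backend!r}")


def fit_outcome_model(data: ObservedDataset, spec, seed: int = 0):
    """Fit the outcome regression m(A, B, C, L) = E(Y | A, B, C, L).

    ``spec`` is a formula string (parametric logistic) or a mapping naming a
    registered back-end (``logistic`` or ``gbt``) with its hyperparameters.
    """
    return _make_outcome(spec, seed=seed).fit(data)


def fit_exposure_models(data: ObservedDataset, specA, specB):
    """Fit p(A | C, L) and p(B | A, C, L) over their finite supports.

    Back-ends: ``saturated`` (empirical pmfs on exact discrete strata),
    ``binomial`` (Binomial-logistic with size = max support), ``multinomial``
    and ``multinomial_spline``. The B model conditions on A as a covariate
    and can be evaluated at counterfactual A levels.
    """
    return _make_exposure(specA, "A").fit(data), _make_exposure(specB, "B").fit(data)


def crossfit_nuisances(
    data: ObservedDataset,
    outcome_spec,
    specA,
    specB,
    K: int = 1,
    seed: int = 0,
) -> NuisanceSet:
    """Fit all three nuisances, optionally with K-fold cross-fitting.

    With ``K = 1`` everything is fitted on the full sample. With ``K >= 2``
    the records are split deterministically given ``seed``; each record's
    predictions come from models trained on the other folds.
    """
    if K < 1 or K > data.n:
        raise ValueError("need 1 <= K <= n")
    if K == 1:
        outcome = fit_outcome_model(data, outcome_spec, seed=seed)
        expA, expB = fit_exposure_models(data, specA, specB)
        return NuisanceSet(outcome=outcome, expA=expA, expB=expB, crossfit_folds=1)

    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(data.n) % K)
    o_models, a_models, b_models = [], [], []
    for k in range(K):
        train = data.subset(np.flatnonzero(fold != k))
        o_models.append(fit_outcome_model(train, outcome_spec, seed=seed + k))
        ma, mb = fit_exposure_models(train, specA, specB)
        a_models.append(ma)
        b_models.append(mb)
    return NuisanceSet(
        outcome=_CrossFitOutcome(o_models, fold),
        expA=_CrossFitExposure(a_models, fold),
        expB=_CrossFitExposure(b_models, fold),
        crossfit_folds=K,
        fold_assignment=fold,
    )
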