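"""Scikit-learn style estimator facade.

``CompositeSEM`` wraps the declarative model description, parameter-table
construction and covariance-structure ML fit behind the familiar
``fit`` / ``transform`` / ``get_params`` surface.  ``transform`` returns
composite scores (the weighted component combinations the model
recovered), so the estimator composes with sklearn pipelines as a
model-based dimension-reduction step.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .builders import (
    build_ho_specification,
    build_one_step_specification,
    build_structural_specification,
)
from .covariance import two_step_reduce
from .exceptions import InputError, SpecificationError
from .fit import (
    fit_ml,
    recover_weights,
    standardized_solution,
    standardized_weights,
    weights_se,
)
from .fitstats import compute_fit_indices
from .io import load_model_config, model_spec_from_dict
from .model import ModelSpec, one_step_spec, two_step_spec
from .moments import SampleMoments, moments_from_data


class CompositeSEM(BaseEstimator, TransformerMixin):
    """Structural equation model with composites (emergent variables).

    Parameters
    ----------
    model:
        A :class:`~compositesem.model.ModelSpec`, a config dict, or a
        path to a YAML model config.
    variant:
        ``"free"``, ``"unit"``, ``"relaxed"`` (Henseler-Ogasawara
        specifications), ``"one_step"`` or ``"two_step"`` (baselines).
    scale_method:
        Scale fixing for the composite of interest in free-weight H-O
        variants: ``"effects"`` (sum of loadings = 1), ``"reference"``
        or ``"variance_std"``.
    divisor:
        Divisor convention used when computing moments from raw data.
    seed:
        Seed for the jittered restarts of the optimizer.

    Attributes
    ----------
    table_ : ParameterTable
        The identified parameter table that was fitted.
    result_ : FitResult
        Estimates, implied covariance, convergence information.
    indices_ : FitIndices
        chi-square test, RMSEA, SRMR, CFI, TLI, AIC/BIC/SABIC.
    weights_ : pandas.DataFrame
        Unstandardized composite weights (rows: components).
    """

    def __init__(
        self,
        model=None,
        *,
        variant: str = "free",
        scale_method: str = "effects",
        divisor: str = "ml",
        seed: int = 0,
    ):
        self.model = model
        self.variant = variant
        self.scale_method = scale_method
        self.divisor = divisor
        self.seed = seed

    # -- helpers -----------------------------------------------------
    def _spec(self) -> ModelSpec:
        if isinstance(self.model, ModelSpec):
            return self.model
        if isinstance(self.model, dict):
            return model_spec_from_dict(self.model)
        if isinstance(self.model, (str, bytes)) or hasattr(self.model, "__fspath__"):
            return load_model_config(self.model)
        raise SpecificationError("`model` must be a ModelSpec, dict or config path")

    def _as_moments(self, X) -> SampleMoments:
        if isinstance(X, SampleMoments):
            return X
        if isinstance(X, pd.DataFrame):
            spec = self._spec()
            missing = set(spec.observed_names) - set(map(str, X.columns))
            if missing:
                raise InputError(f"data is missing columns {sorted(missing)}")
            return moments_from_data(
                X[list(spec.observed_names)], divisor=self.divisor
            )
        X = np.asarray(X, dtype=float)
        spec = self._spec()
        if X.ndim != 2 or X.shape[1] != len(spec.observed_names):
            raise InputError(
                f"expected {len(spec.observed_names)} columns in the order "
                f"{spec.observed_names}"
            )
        return moments_from_data(
            pd.DataFrame(X, columns=list(spec.observed_names)), divisor=self.divisor
        )

    # -- estimation --------------------------------------------------
    def fit(self, X, y=None):
        """Fit the model to raw data (rows = observations) or to a
        :class:`SampleMoments` object."""
        spec = self._spec()
        spec.validate()
        moments = self._as_moments(X)
        variant = self.variant

        if variant == "two_step":
            reduced = two_step_reduce(
                moments.reorder(spec.observed_names), spec.blocks
            )
            table = build_structural_specification(
                two_step_spec(spec), moments=reduced
            )
            fit = fit_ml(table, reduced, seed=self.seed)
            weights = {
                b.name: pd.Series(
                    np.ones(len(b.components)), index=list(b.components)
                )
                for b in spec.blocks
            }
        elif variant == "one_step":
            table = build_one_step_specification(
                one_step_spec(spec), moments=moments
            )
            fit = fit_ml(table, moments, seed=self.seed)
            A, _ = fit.compiled.resolve(fit.theta)
            weights = {
                b.name: pd.Series(
                    [
                        A[fit.compiled.index[b.name], fit.compiled.index[c]]
                        for c in b.components
                    ],
                    index=list(b.components),
                )
                for b in spec.blocks
            }
        elif variant in ("free", "unit", "relaxed"):
            table = build_ho_specification(
                spec, variant, moments=moments, scale_method=self.scale_method
            )
            fit = fit_ml(table, moments, seed=self.seed)
            weights = {
                b.name: recover_weights(fit, b.name) for b in spec.blocks
            }
        else:
            raise SpecificationError(f"unknown variant {variant!r}")

        self.spec_ = spec
        self.table_ = table
        self.result_ = fit
        self.estimates_ = dict(fit.estimates)
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.implied_cov_ = fit.sigma
        self.chi2_ = fit.moments.n * fit.f_min
        self.dof_ = fit.dof
        self.indices_ = compute_fit_indices(fit)
        self.weights_ = pd.DataFrame(weights)
        if variant in ("free", "unit", "relaxed"):
            self.std_weights_ = pd.DataFrame(
                {b.name: standardized_weights(fit, b.name) for b in spec.blocks}
            )
            self.weights_se_ = pd.DataFrame(
                {b.name: weights_se(fit, b.name) for b in spec.blocks}
            )
        self.n_features_in_ = len(spec.observed_names)
        self.feature_names_in_ = np.asarray(spec.observed_names, dtype=object)
        return self

    def standardized_solution_(self, with_se: bool = True) -> pd.DataFrame:
        self._check_fitted()
        return standardized_solution(self.result_, with_se=with_se)

    # -- transform ---------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Composite scores ``c = w' x`` for each block (columns in block
        order); non-component variables are not passed through."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != self.n_features_in_:
                raise InputError(
                    f"X has {X.shape[1]} features, expected {self.n_features_in_}"
                )
        names = list(self.feature_names_in_)
        out = np.zeros((X.shape[0], len(self.spec_.blocks)))
        for bi, b in enumerate(self.spec_.blocks):
            w = self.weights_[b.name].reindex(list(b.components))
            idx = [names.index(c) for c in b.components]
            out[:, bi] = X[:, idx] @ w.to_numpy()
        return out

    def get_feature_names_out(self, input_features=None):
        self._check_fitted()
        return np.asarray([b.name for b in self.spec_.blocks], dtype=object)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise NotFittedError(
                "This CompositeSEM instance is not fitted yet; call `fit` first."
            )
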