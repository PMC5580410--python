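"""End-to-end wiring: data -> models -> constrained optimization problem.

The inverse-QSAR objective maximizes the SVR-predicted activity, so the
minimized objective is f(x) = -prediction.  The applicability domain
enters as the inequality g1(x) = -AD_score(x) (feasible iff the OCSVM
output is >= 0), and descriptor-consistency rules add further
inequalities evaluated in unscaled units.  Optimization runs in the
[-1, 1] range-scaled space with box bounds at the training min/max;
discrete descriptors are rounded in unscaled units and mapped back.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .compounds import ConstraintRule, build_constraints
from .models import (
    ActivityRegressor,
    ApplicabilityDomain,
    CVConfig,
    RangeScaler,
    SVRHyperParams,
    fit_regression,
    select_svr_hyperparameters,
)
from .optimize import COProblem, DEParams, OptimizationResult, evolve, round_discrete


@dataclasses.dataclass
class FittedModels:
    """The scaler/regressor/AD triple fitted on one training set."""

    scaler: RangeScaler
    regressor: ActivityRegressor
    ad: ApplicabilityDomain
    svr_params: SVRHyperParams
    cv_q2: float


def fit_qsar_models(
    X_train,
    y_train,
    cv: Optional[CVConfig] = None,
    ad_nu: float = 0.01,
) -> FittedModels:
    """Fit the range scaler, CV-selected ν-SVR and OCSVM AD on training data."""
    X_train = np.asarray(X_train, dtype=float)
    scaler = RangeScaler().fit(X_train)
    Z = scaler.transform(X_train)
    params, q2 = select_svr_hyperparameters(Z, y_train, cv=cv, return_score=True)
    regressor = fit_regression(Z, np.asarray(y_train, dtype=float), params)
    ad = ApplicabilityDomain(nu=ad_nu).fit(Z)
    return FittedModels(scaler=scaler, regressor=regressor, ad=ad, svr_params=params, cv_q2=q2)


def build_inverse_qsar_problem(
    models: FittedModels,
    discrete_mask: Optional[np.ndarray] = None,
    rules: Sequence[ConstraintRule] = (),
    columns: Optional[Sequence[str]] = None,
) -> COProblem:
    """Assemble the COP in scaled descriptor space.

    Bounds are the scaled training range, i.e. [-1, 1] per dimension.
    Descriptor rules require ``columns`` naming the descriptor order.
    """
    d = models.scaler.n_features_in_
    bounds = np.column_stack([np.full(d, -1.0), np.full(d, 1.0)])

    def objective(Z):
        return -models.regressor.predict(np.atleast_2d(Z))

    def ad_constraint(Z):
        return -models.ad.decision_function(np.atleast_2d(Z))

    inequalities = [ad_constraint]
    if rules:
        if columns is None:
            raise ValueError("descriptor rules require column names")
        for g_unscaled in build_constraints(rules, columns):
            def g(Z, g_unscaled=g_unscaled):
                X = models.scaler.inverse_transform(np.atleast_2d(Z))
                return g_unscaled(X)

            inequalities.append(g)

    quantize = None
    if discrete_mask is not None and np.asarray(discrete_mask, dtype=bool).any():
        mask = np.asarray(discrete_mask, dtype=bool)

        def quantize(Z):
            X = models.scaler.inverse_transform(np.atleast_2d(Z))
            return models.scaler.transform(round_discrete(X, mask))

    return COProblem(
        objective=objective,
        bounds=bounds,
        inequalities=inequalities,
        discrete_mask=None if discrete_mask is None else np.asarray(discrete_mask, dtype=bool),
        quantize=quantize,
    )


@dataclasses.dataclass
class CoordinateOptimization:
    """Optimized coordinates with model context."""

    result: OptimizationResult
    x_scaled: np.ndarray
    x_unscaled: np.ndarray
    predicted_activity: float
    ad_score: float

    @property
    def feasible(self) -> bool:
        return self.result.feasible


def optimize_coordinates(
    models: FittedModels,
    X_train,
    de_params: Optional[DEParams] = None,
    discrete_mask: Optional[np.ndarray] = None,
    rules: Sequence[ConstraintRule] = (),
    columns: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> CoordinateOptimization:
    """Run εDE from the training vectors and report the optimized point.

    The initial population is the scaled training matrix, mirroring the
    protocol of seeding the search with the training instances themselves.
    """
    de_params = de_params if de_params is not None else DEParams()
    problem = build_inverse_qsar_problem(
        models, discrete_mask=discrete_mask, rules=rules, columns=columns
    )
    Z0 = models.scaler.transform(np.asarray(X_train, dtype=float))
    result = evolve(problem, de_params, Z0, rng=rng)
    z = result.best.x
    x = models.scaler.inverse_transform(z.reshape(1, -1))[0]
    return CoordinateOptimization(
        result=result,
        x_scaled=z,
        x_unscaled=x,
        predicted_activity=float(models.regressor.predict(z.reshape(1, -1))[0]),
        ad_score=float(models.ad.decision_function(z.reshape(1, -1))[0]),
    )
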