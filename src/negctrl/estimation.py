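"""OLS fit of the (misspecified) observed-data regression.

The analyst's model regresses the outcome on the observed exposure and
observed control, with an intercept:

    y_i = b0 + b1 * E_O,i + b2 * C_O,i + residual

The confounder is omitted and the regressors carry measurement error,
so the fitted coefficients are biased estimates of the structural
(beta1, beta2); quantifying that bias is the whole point of the
surrounding package.  An intercept is always included: dichotomised
regressors have nonzero means, and without the intercept the no-error,
no-confounding design would itself be misspecified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import StructuralParams
from .synthetic_data import ObservedData

__all__ = ["FitResult", "DegenerateDesignError", "fit_observed_regression", "coefficient_errors"]


class DegenerateDesignError(ValueError):
    """Raised when the design matrix is rank deficient.

    Typical cause in simulation: a binary regressor landing entirely in
    one class, or exposure and control exactly collinear.  Callers
    running replicated simulations drop and count such replicates.
    """


@dataclass(frozen=True)
class FitResult:
    """OLS coefficients of the observed-data regression."""

    b1_hat: float
    b2_hat: float
    intercept: float
    n: int


def fit_observed_regression(data: ObservedData) -> FitResult:
    """Least-squares fit of y on (1, E_O, C_O).

    Solved via ``numpy.linalg.lstsq`` on the raw design matrix.  The
    rank reported by the solver is checked; a rank-deficient design
    raises :class:`DegenerateDesignError` rather than returning an
    arbitrary minimum-norm solution.
    """
    n = data.n
    if n <= 3:
        raise DegenerateDesignError(f"need n > 3 observations, got {n}")
    X = np.column_stack([np.ones(n), data.E_O, data.C_O])
    coef, _, rank, _ = np.linalg.lstsq(X, data.y, rcond=None)
    if rank < 3:
        raise DegenerateDesignError(
            "design matrix is rank deficient (constant or collinear regressors)"
        )
    return FitResult(
        b1_hat=float(coef[1]), b2_hat=float(coef[2]), intercept=float(coef[0]), n=n
    )


def coefficient_errors(fit: FitResult, sp: StructuralParams) -> tuple[float, float, float]:
    """Estimation errors (b1_hat - beta1, b2_hat - beta2, and their contrast).

    The third component is the error of ``b1_hat - b2_hat`` as an
    estimator of ``beta1 - beta2``; it equals the first minus the second
    by construction.
    """
    e1 = fit.b1_hat - sp.beta1
    e2 = fit.b2_hat - sp.beta2
    return (e1, e2, e1 - e2)
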