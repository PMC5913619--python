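"""Model parameters and asymptotic moment matrices.

The structural model is

    y_i = beta1 * E_T,i + beta2 * C_T,i + gamma * U_i + eps_i

where ``E_T`` is the true exposure, ``C_T`` the true negative control and
``U`` an unmeasured confounder.  All three latent variables have unit
variance; ``U`` correlates ``rho_UE`` with the exposure and ``rho_UC``
with the control, and the exposure and control are correlated only
through the confounder, so ``rho_EC = rho_UE * rho_UC``.

Measurement error is described either on the continuous scale via
intraclass correlation coefficients (ICC = true variance / observed
variance) or, for dichotomised designs, via symmetric misclassification
proportions.

All dataclasses validate on construction; downstream code assumes
well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "StructuralParams",
    "ConfoundingStructure",
    "ContinuousErrorSpec",
    "BinaryErrorSpec",
    "MomentMatrices",
    "derive_rho_ec",
    "icc_to_error_variance",
    "error_variance_to_icc",
    "build_moment_matrices",
]


class ValidationError(ValueError):
    """Raised when a parameter value violates the model's constraints."""


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class StructuralParams:
    """True causal coefficients of the outcome model.

    Parameters
    ----------
    beta1
        Causal effect of the exposure on the outcome.
    beta2
        Causal effect of the negative control on the outcome.  A genuine
        negative control has ``beta2 = 0``.
    gamma
        Effect of the unmeasured confounder on the outcome.
    sigma_eps
        Standard deviation of the outcome noise term (default 1).  The
        asymptotic bias does not depend on it; only Monte Carlo noise does.
    """

    beta1: float
    beta2: float
    gamma: float = 0.0
    sigma_eps: float = 1.0

    def __post_init__(self) -> None:
        _require_finite(
            beta1=self.beta1, beta2=self.beta2, gamma=self.gamma, sigma_eps=self.sigma_eps
        )
        if self.sigma_eps <= 0:
            raise ValidationError(f"sigma_eps must be > 0, got {self.sigma_eps}")

    @property
    def beta(self) -> np.ndarray:
        """The coefficient vector (beta1, beta2)."""
        return np.array([self.beta1, self.beta2], dtype=float)


def derive_rho_ec(rho_UE: float, rho_UC: float) -> float:
    """Correlation between true exposure and control induced by the confounder.

    Under the assumption that the exposure and the negative control are
    correlated only through the unmeasured confounder,
    ``rho_EC = rho_UE * rho_UC``.

    Raises
    ------
    ValidationError
        If either input lies outside (-1, 1), is not finite, or the
        implied 3x3 correlation matrix of (U, E_T, C_T) is not positive
        definite.
    """
    _require_finite(rho_UE=rho_UE, rho_UC=rho_UC)
    for name, value in (("rho_UE", rho_UE), ("rho_UC", rho_UC)):
        if not -1.0 < value < 1.0:
            raise ValidationError(f"{name} must lie in (-1, 1), got {value}")
    rho_ec = rho_UE * rho_UC
    corr = _latent_correlation_matrix(rho_UE, rho_UC, rho_ec)
    if np.linalg.eigvalsh(corr)[0] <= 0:
        raise ValidationError(
            "implied (U, E_T, C_T) correlation matrix is not positive definite"
        )
    return rho_ec


def _latent_correlation_matrix(rho_UE: float, rho_UC: float, rho_EC: float) -> np.ndarray:
    return np.array(
        [
            [1.0, rho_UE, rho_UC],
            [rho_UE, 1.0, rho_EC],
            [rho_UC, rho_EC, 1.0],
        ]
    )


@dataclass(frozen=True)
class ConfoundingStructure:
    """Correlations between the unmeasured confounder and the regressors.

    ``rho_EC`` is derived, never supplied: the model assumes no direct
    exposure-control dependence, so the only channel is the confounder.
    """

    rho_UE: float
    rho_UC: float
    rho_EC: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho_EC", derive_rho_ec(self.rho_UE, self.rho_UC))

    def correlation_matrix(self) -> np.ndarray:
        """3x3 correlation matrix of (U, E_T, C_T)."""
        return _latent_correlation_matrix(self.rho_UE, self.rho_UC, self.rho_EC)


def icc_to_error_variance(icc: float, sigma2_true: float = 1.0) -> float:
    """Measurement-error variance implied by an intraclass correlation.

    Solves ``ICC = sigma2_true / (sigma2_true + sigma2_v)`` for
    ``sigma2_v``, giving ``sigma2_true * (1 - ICC) / ICC``.  An ICC of 1
    means error-free measurement (zero error variance).

    Raises
    ------
    ValidationError
        For ICC outside (0, 1] (an ICC of 0 would require infinite error
        variance) or non-positive true-score variance.
    """
    _require_finite(icc=icc, sigma2_true=sigma2_true)
    if not 0.0 < icc <= 1.0:
        raise ValidationError(f"icc must lie in (0, 1], got {icc}")
    if sigma2_true <= 0:
        raise ValidationError(f"sigma2_true must be > 0, got {sigma2_true}")
    return sigma2_true * (1.0 - icc) / icc


def error_variance_to_icc(sigma2_v: float, sigma2_true: float = 1.0) -> float:
    """Inverse of :func:`icc_to_error_variance`."""
    _require_finite(sigma2_v=sigma2_v, sigma2_true=sigma2_true)
    if sigma2_v < 0:
        raise ValidationError(f"sigma2_v must be >= 0, got {sigma2_v}")
    if sigma2_true <= 0:
        raise ValidationError(f"sigma2_true must be > 0, got {sigma2_true}")
    return sigma2_true / (sigma2_true + sigma2_v)


@dataclass(frozen=True)
class ContinuousErrorSpec:
    """Additive normal measurement error on both regressors, via ICCs.

    With unit true-score variance, the error variances are
    ``sigma2_v = (1 - ICC) / ICC`` per variable.
    """

    icc_E: float = 1.0
    icc_C: float = 1.0
    sigma2_true: float = 1.0
    sigma2_vE: float = field(init=False)
    sigma2_vC: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma2_vE", icc_to_error_variance(self.icc_E, self.sigma2_true))
        object.__setattr__(self, "sigma2_vC", icc_to_error_variance(self.icc_C, self.sigma2_true))


@dataclass(frozen=True)
class BinaryErrorSpec:
    """Symmetric misclassification of dichotomised regressors.

    ``p_E`` and ``p_C`` are the proportions of observations whose
    recorded class is flipped, applied with the same rate in both
    classes (non-differential).  ``quantile_cut`` is the quantile of the
    latent variable above which observations are coded 1; the default
    0.8 codes the top 20% as exposed.
    """

    p_E: float = 0.0
    p_C: float = 0.0
    quantile_cut: float = 0.8

    def __post_init__(self) -> None:
        _require_finite(p_E=self.p_E, p_C=self.p_C, quantile_cut=self.quantile_cut)
        for name, value in (("p_E", self.p_E), ("p_C", self.p_C)):
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.quantile_cut < 1.0:
            raise ValidationError(
                f"quantile_cut must lie strictly inside (0, 1), got {self.quantile_cut}"
            )


@dataclass(frozen=True)
class MomentMatrices:
    """Asymptotic second moments of the true regressors and the confounder.

    ``Q_XX`` is the probability limit of ``X_T' X_T / n`` (unit diagonal,
    off-diagonal ``rho_EC``), ``Q_XU`` the limit of ``X_T' U / n``
    (the vector ``(rho_UE, rho_UC)``), and ``Sigma_v`` the diagonal
    matrix of measurement-error variances.
    """

    Q_XX: np.ndarray
    Q_XU: np.ndarray
    Sigma_v: np.ndarray

    def __post_init__(self) -> None:
        Q_XX = np.asarray(self.Q_XX, dtype=float)
        Q_XU = np.asarray(self.Q_XU, dtype=float).reshape(2)
        Sigma_v = np.asarray(self.Sigma_v, dtype=float)
        if Q_XX.shape != (2, 2) or Sigma_v.shape != (2, 2):
            raise ValidationError("Q_XX and Sigma_v must be 2x2 matrices")
        if not np.allclose(Q_XX, Q_XX.T):
            raise ValidationError("Q_XX must be symmetric")
        if np.linalg.eigvalsh(Q_XX)[0] <= 0:
            raise ValidationError("Q_XX must be positive definite")
        if not np.allclose(Sigma_v, np.diag(np.diag(Sigma_v))):
            raise ValidationError("Sigma_v must be diagonal (uncorrelated errors)")
        if np.any(np.diag(Sigma_v) < 0):
            raise ValidationError("Sigma_v diagonal entries must be nonnegative")
        object.__setattr__(self, "Q_XX", Q_XX)
        object.__setattr__(self, "Q_XU", Q_XU)
        object.__setattr__(self, "Sigma_v", Sigma_v)


def build_moment_matrices(
    conf: ConfoundingStructure, err: ContinuousErrorSpec | None = None
) -> MomentMatrices:
    """Assemble the moment matrices of the continuous-design asymptotics.

    With unit true-score variances, ``Q_XX = [[1, rho_EC], [rho_EC, 1]]``,
    ``Q_XU = (rho_UE, rho_UC)`` and ``Sigma_v = diag(sigma2_vE,
    sigma2_vC)``.  Passing ``err=None`` means error-free measurement.
    """
    if err is None:
        err = ContinuousErrorSpec()
    q_xx = np.array([[1.0, conf.rho_EC], [conf.rho_EC, 1.0]])
    q_xu = np.array([conf.rho_UE, conf.rho_UC])
    sigma_v = np.diag([err.sigma2_vE, err.sigma2_vC])
    return MomentMatrices(Q_XX=q_xx, Q_XU=q_xu, Sigma_v=sigma_v)
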