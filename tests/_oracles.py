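"""Independent oracles used by the test suite.

These routines deliberately avoid the package's own code paths: the
binary-design population bias is computed from exact bivariate-normal
orthant probabilities, and the OLS cross-checks use statsmodels and raw
normal equations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm


def binary_population_bias(
    p_E: float,
    p_C: float,
    beta1: float = 0.0,
    beta2: float = 0.0,
    gamma: float = 0.2,
    rho: float = 0.4,
    cut: float = 0.8,
) -> tuple[float, float, float]:
    """Exact asymptotic bias in the dichotomised design.

    Population moments of the dichotomised, misclassified regressors are
    derived in closed form: for a standard normal X cut at c,
    E[U 1{X>c}] = rho_XU * phi(c); the joint exceedance P(X>c, Y>c)
    comes from the bivariate normal CDF; symmetric misclassification at
    rate p scales every covariance of the variable by (1 - 2p) and sets
    the variance to that of a Bernoulli with the mixed prevalence.  The
    population OLS slopes (with intercept) then follow from the 2x2
    covariance system.
    """
    c = norm.ppf(cut)
    p1 = 1.0 - cut
    cov_bU = rho * norm.pdf(c)  # true binary vs confounder
    rho_ec = rho * rho
    p11 = multivariate_normal(mean=[0, 0], cov=[[1, rho_ec], [rho_ec, 1]]).cdf([-c, -c])
    cov_bb = p11 - p1 * p1  # true binary exposure vs true binary control
    var_b = p1 * (1.0 - p1)

    def prevalence(p: float) -> float:
        return p1 * (1.0 - p) + (1.0 - p1) * p

    mE, mC = prevalence(p_E), prevalence(p_C)
    vE, vC = mE * (1.0 - mE), mC * (1.0 - mC)
    aE, aC = 1.0 - 2.0 * p_E, 1.0 - 2.0 * p_C
    cov_EC = aE * aC * cov_bb
    cov_Ey = beta1 * aE * var_b + beta2 * aE * cov_bb + gamma * aE * cov_bU
    cov_Cy = beta1 * aC * cov_bb + beta2 * aC * var_b + gamma * aC * cov_bU
    S = np.array([[vE, cov_EC], [cov_EC, vC]])
    slopes = np.linalg.solve(S, [cov_Ey, cov_Cy])
    return float(slopes[0] - beta1), float(slopes[1] - beta2), float(
        slopes[0] - beta1 - (slopes[1] - beta2)
    )


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force OLS via the normal equations (test oracle only)."""
    return np.linalg.solve(X.T @ X, X.T @ y)
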