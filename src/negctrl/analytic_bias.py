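"""Closed-form asymptotic bias of OLS with mismeasured, confounded regressors.

Regressing the outcome on the observed (error-laden) exposure and
negative control while omitting the confounder yields the asymptotic
coefficient bias

    E[b_hat - beta] = (Q_XX + Sigma_v)^{-1} Q_XU * gamma
                      - (Q_XX + Sigma_v)^{-1} Sigma_v * beta

The first term is omitted-variable (confounding) bias; the second is
regression-dilution bias from the measurement error.  The bias of the
calibrated contrast ``b1_hat - b2_hat`` is the difference of the two
components, and is zero only when both the confounding paths and the
error levels are matched between exposure and control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ConfoundingStructure,
    ContinuousErrorSpec,
    MomentMatrices,
    StructuralParams,
    build_moment_matrices,
)

__all__ = [
    "BiasResult",
    "analytic_ols_bias",
    "univariate_attenuation",
    "bias_curve",
    "DEFAULT_GAMMA_GRID",
    "plot_bias_curves",
]

#: 51 evenly spaced confounder-effect values on [0, 0.5], the range the
#: bias curves are drawn over.
DEFAULT_GAMMA_GRID: np.ndarray = np.linspace(0.0, 0.5, 51)


@dataclass(frozen=True)
class BiasResult:
    """Bias of the OLS coefficients and of their difference.

    ``bias_diff`` is the bias of ``b1_hat - b2_hat`` as an estimator of
    ``beta1 - beta2`` and always equals ``bias_b1 - bias_b2``.  Monte
    Carlo standard errors are present iff ``method == 'monte_carlo'``.
    """

    bias_b1: float
    bias_b2: float
    bias_diff: float
    method: str  # 'analytic' or 'monte_carlo'
    mc_se_b1: float | None = None
    mc_se_b2: float | None = None
    mc_se_diff: float | None = None
    reps_used: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("analytic", "monte_carlo"):
            raise ValueError(f"unknown method {self.method!r}")
        has_se = self.mc_se_b1 is not None
        if has_se != (self.method == "monte_carlo"):
            raise ValueError("MC standard errors present iff method == 'monte_carlo'")


def analytic_ols_bias(M: MomentMatrices, sp: StructuralParams) -> BiasResult:
    """Evaluate the asymptotic OLS bias from the moment matrices.

    The linear system ``(Q_XX + Sigma_v) b = Q_XU * gamma - Sigma_v * beta``
    is solved directly rather than forming an explicit inverse, for
    stability when ``rho_EC`` approaches +/-1.

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``Q_XX + Sigma_v`` is singular.
    """
    A = M.Q_XX + M.Sigma_v
    rhs = M.Q_XU * sp.gamma - M.Sigma_v @ sp.beta
    try:
        bias = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError(
            f"Q_XX + Sigma_v is singular (condition number {np.linalg.cond(A):.3g})"
        ) from exc
    return BiasResult(
        bias_b1=float(bias[0]),
        bias_b2=float(bias[1]),
        bias_diff=float(bias[0] - bias[1]),
        method="analytic",
    )


def univariate_attenuation(beta1: float, sigma2_v: float) -> float:
    """Classical regression-dilution limit for a single mismeasured regressor.

    With unit true-score variance, no confounding and no second
    regressor, the OLS slope converges to ``beta1 / (1 + sigma2_v)``
    (reliability ratio times the true slope).  Used as an independent
    oracle for the degenerate case of :func:`analytic_ols_bias`.
    """
    if sigma2_v < 0:
        raise ValueError(f"sigma2_v must be >= 0, got {sigma2_v}")
    return beta1 / (1.0 + sigma2_v)


def bias_curve(
    sp_base: StructuralParams,
    conf: ConfoundingStructure,
    err_grid: Sequence[ContinuousErrorSpec],
    gamma_grid: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Asymptotic bias as a function of the confounder effect gamma.

    For each measurement-error configuration and each gamma on the grid
    (``gamma`` overrides ``sp_base.gamma``), evaluates the closed-form
    bias.  Returns a tidy table with one row per (error config, gamma)
    pair, ordered for plotting or CSV export.

    Columns: gamma, icc_E, icc_C, beta1, beta2, bias_b1, bias_b2,
    bias_diff, method.
    """
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    gammas = np.asarray(list(gamma_grid), dtype=float)
    err_grid = list(err_grid)
    if len(err_grid) == 0 or gammas.size == 0:
        raise ValueError("err_grid and gamma_grid must be nonempty")

    rows = []
    for err in err_grid:
        M = build_moment_matrices(conf, err)
        for gamma in gammas:
            sp = StructuralParams(
                beta1=sp_base.beta1,
                beta2=sp_base.beta2,
                gamma=float(gamma),
                sigma_eps=sp_base.sigma_eps,
            )
            res = analytic_ols_bias(M, sp)
            rows.append(
                {
                    "gamma": float(gamma),
                    "icc_E": err.icc_E,
                    "icc_C": err.icc_C,
                    "beta1": sp.beta1,
                    "beta2": sp.beta2,
                    "bias_b1": res.bias_b1,
                    "bias_b2": res.bias_b2,
                    "bias_diff": res.bias_diff,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def plot_bias_curves(curve: pd.DataFrame, path: str) -> None:
    """Plot bias versus gamma, one panel per error configuration.

    Each panel shows the bias of b1_hat, b2_hat and of the calibrated
    contrast b1_hat - b2_hat over the gamma grid.  Saved to ``path``
    (format inferred from the extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    configs = list(curve.groupby(["icc_E", "icc_C"], sort=False))
    ncol = min(len(configs), 2)
    nrow = -(-len(configs) // ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(5.0 * ncol, 3.2 * nrow), squeeze=False, sharex=True
    )
    for ax, ((icc_e, icc_c), sub) in zip(axes.ravel(), configs):
        ax.plot(sub["gamma"], sub["bias_b1"], label=r"bias $\hat\beta_1$")
        ax.plot(sub["gamma"], sub["bias_b2"], label=r"bias $\hat\beta_2$")
        ax.plot(sub["gamma"], sub["bias_diff"], label=r"bias $\hat\beta_1-\hat\beta_2$")
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_title(f"ICC exposure = {icc_e}, ICC control = {icc_c}")
        ax.set_xlabel(r"$\gamma$")
        ax.set_ylabel("bias")
    for ax in axes.ravel()[len(configs):]:
        ax.set_visible(False)
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
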