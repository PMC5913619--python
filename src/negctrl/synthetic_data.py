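"""Seeded generation of individual-level data from the structural model.

The latent triple (U, E_T, C_T) is drawn from a trivariate standard
normal with the configured correlation structure.  Observation layers
are applied on top:

* continuous design — additive, independent normal measurement error on
  the true exposure and control;
* binary design — the true values are dichotomised at an empirical
  quantile (top 20% coded 1 by default), then a proportion of recorded
  classes is flipped symmetrically.

The outcome is always generated from the *true* (error-free) regressors;
measurement error only degrades what the analyst observes, never the
data-generating process.  Every function is deterministic given its
seed, and independent channels (latents, each error channel, outcome
noise) use independently derived streams so that toggling one does not
perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    BinaryErrorSpec,
    ConfoundingStructure,
    ContinuousErrorSpec,
    StructuralParams,
    ValidationError,
)

__all__ = [
    "LatentSample",
    "ObservedData",
    "draw_latents",
    "add_continuous_error",
    "dichotomize_top_quantile",
    "misclassify",
    "generate_outcome",
    "simulate_continuous",
    "simulate_binary",
    "replicate_seed",
]

SeedLike = int | np.random.SeedSequence | np.random.Generator


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def replicate_seed(master_seed: int, cell_index: int, rep: int) -> np.random.SeedSequence:
    """Seed sequence for one replicate of one scenario cell.

    Derived from ``(master_seed, cell_index, rep)`` via the spawn key,
    so cells and replicates can run in any order (or in parallel) with
    identical results.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index, rep))


@dataclass(frozen=True)
class LatentSample:
    """A draw of the unmeasured confounder and true exposure/control."""

    U: np.ndarray
    E_T: np.ndarray
    C_T: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not (len(self.U) == len(self.E_T) == len(self.C_T) == self.n):
            raise ValidationError("latent vectors must all have length n")


@dataclass(frozen=True)
class ObservedData:
    """What the analyst sees: observed regressors and the outcome."""

    E_O: np.ndarray
    C_O: np.ndarray
    y: np.ndarray
    design: str  # 'continuous' or 'binary'

    def __post_init__(self) -> None:
        if self.design not in ("continuous", "binary"):
            raise ValidationError(f"unknown design {self.design!r}")
        if not (len(self.E_O) == len(self.C_O) == len(self.y)):
            raise ValidationError("observed vectors must have equal length")
        if self.design == "binary":
            for name, x in (("E_O", self.E_O), ("C_O", self.C_O)):
                if not np.isin(x, (0.0, 1.0)).all():
                    raise ValidationError(f"{name} must be 0/1 in the binary design")

    @property
    def n(self) -> int:
        return len(self.y)


def draw_latents(n: int, conf: ConfoundingStructure, seed: SeedLike) -> LatentSample:
    """Draw (U, E_T, C_T) jointly normal with unit variances.

    The correlation matrix is ``conf.correlation_matrix()``; positive
    definiteness is guaranteed by ``ConfoundingStructure`` validation.
    """
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    rng = _rng(seed)
    L = np.linalg.cholesky(conf.correlation_matrix())
    Z = rng.standard_normal((n, 3)) @ L.T
    return LatentSample(U=Z[:, 0], E_T=Z[:, 1], C_T=Z[:, 2], n=n)


def add_continuous_error(x_true: np.ndarray, sigma2_v: float, seed: SeedLike) -> np.ndarray:
    """Add independent mean-zero normal error with variance ``sigma2_v``."""
    if sigma2_v < 0:
        raise ValidationError(f"sigma2_v must be >= 0, got {sigma2_v}")
    x_true = np.asarray(x_true, dtype=float)
    if sigma2_v == 0:
        return x_true.copy()
    rng = _rng(seed)
    return x_true + rng.normal(0.0, np.sqrt(sigma2_v), size=x_true.shape)


def dichotomize_top_quantile(x: np.ndarray, cut: float = 0.8) -> np.ndarray:
    """Code the values above the empirical ``cut`` quantile as 1, rest as 0.

    With the default cut of 0.8 the top 20% of values are coded 1.  The
    threshold is the empirical quantile of the input itself, so any
    strictly monotone transform of ``x`` yields the same coding.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot dichotomize an empty vector")
    if not 0.0 < cut < 1.0:
        raise ValidationError(f"cut must lie in (0, 1), got {cut}")
    if np.min(x) == np.max(x):
        raise ValidationError("cannot dichotomize a constant vector")
    threshold = np.quantile(x, cut)
    return (x > threshold).astype(float)


def misclassify(x: np.ndarray, p: float, seed: SeedLike) -> np.ndarray:
    """Flip each 0/1 entry independently with probability ``p``.

    The flip rate is identical in both classes (symmetric,
    non-differential misclassification), which attenuates the covariance
    of the variable with anything else by the factor ``1 - 2p``.
    """
    x = np.asarray(x, dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError("misclassify requires a 0/1 vector")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if p == 0:
        return x.copy()
    rng = _rng(seed)
    flip = rng.random(x.shape) < p
    return np.where(flip, 1.0 - x, x)


def generate_outcome(
    ls: LatentSample,
    sp: StructuralParams,
    E_for_y: np.ndarray,
    C_for_y: np.ndarray,
    seed: SeedLike,
) -> np.ndarray:
    """Generate ``y = beta1*E + beta2*C + gamma*U + eps``.

    ``E_for_y`` and ``C_for_y`` are the true regressors entering the
    structural equation: the continuous true scores in the continuous
    design, the dichotomised (pre-misclassification) values in the
    binary design.
    """
    E_for_y = np.asarray(E_for_y, dtype=float)
    C_for_y = np.asarray(C_for_y, dtype=float)
    if len(E_for_y) != ls.n or len(C_for_y) != ls.n:
        raise ValidationError("E_for_y and C_for_y must have length n")
    rng = _rng(seed)
    eps = rng.normal(0.0, sp.sigma_eps, size=ls.n)
    return sp.beta1 * E_for_y + sp.beta2 * C_for_y + sp.gamma * ls.U + eps


def simulate_continuous(
    n: int,
    sp: StructuralParams,
    conf: ConfoundingStructure,
    err: ContinuousErrorSpec,
    seed: SeedLike,
) -> ObservedData:
    """One continuous-design dataset: true model plus additive error.

    The outcome is built from the true scores; the observed exposure and
    control carry independent additive normal error with the variances
    implied by the ICCs.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_lat, s_ve, s_vc, s_eps = ss.spawn(4)
    ls = draw_latents(n, conf, s_lat)
    E_O = add_continuous_error(ls.E_T, err.sigma2_vE, s_ve)
    C_O = add_continuous_error(ls.C_T, err.sigma2_vC, s_vc)
    y = generate_outcome(ls, sp, ls.E_T, ls.C_T, s_eps)
    return ObservedData(E_O=E_O, C_O=C_O, y=y, design="continuous")


def simulate_binary(
    n: int,
    sp: StructuralParams,
    conf: ConfoundingStructure,
    err: BinaryErrorSpec,
    seed: SeedLike,
) -> ObservedData:
    """One binary-design dataset: dichotomise, generate y, then misclassify.

    The latent exposure and control are cut at the empirical
    ``err.quantile_cut`` quantile; the outcome is generated from these
    *true* binary values; misclassification is applied afterwards, to
    the recorded copies only.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_lat, s_fe, s_fc, s_eps = ss.spawn(4)
    ls = draw_latents(n, conf, s_lat)
    E_b = dichotomize_top_quantile(ls.E_T, err.quantile_cut)
    C_b = dichotomize_top_quantile(ls.C_T, err.quantile_cut)
    y = generate_outcome(ls, sp, E_b, C_b, s_eps)
    E_O = misclassify(E_b, err.p_E, s_fe)
    C_O = misclassify(C_b, err.p_C, s_fc)
    return ObservedData(E_O=E_O, C_O=C_O, y=y, design="binary")
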