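"""Design parameterization and closed-form variance algebra.

A two-arm parallel cluster-randomized trial (CRT) with ``n`` clusters of
equal size ``m`` is analyzed with the linear mixed analysis-of-covariance
model

    Y_ij = b1 + b2*Z_i + b3*S_ij + b4*Z_i*S_ij + u_i + e_ij,

where ``Z_i`` is the cluster-level treatment indicator, ``S_ij`` a binary
subgroup (effect-modifier) variable, ``u_i ~ N(0, sigma_b^2)`` a random
cluster intercept and ``e_ij ~ N(0, sigma_e^2)`` residual noise.  The
subgroup-specific treatment effects are ``Delta0 = b2`` (subgroup S=0) and
``Delta1 = b2 + b4`` (subgroup S=1).

This module provides the closed-form (generalized-least-squares) variances
of the estimators of the interaction effect, the overall average treatment
effect (ATE), and the pair of subgroup-specific effects, as functions of
two intracluster correlation coefficients: the outcome ICC ``rho_y``
(conditional on subgroup and treatment) and the subgroup-variable ICC
``rho_s``.  An exact information-matrix oracle over explicit subgroup
layouts is included for verification.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DesignParams",
    "EffectSpec",
    "ModelParams",
    "CovDelta",
    "SingularDesignError",
    "var_hte",
    "var_ate",
    "omega_delta",
    "omega_delta_oracle",
    "implied_subgroup_moments",
]

#: Tolerance used for internal identity checks on the variance algebra.
IDENTITY_TOL = 1e-12

PARTICIPANT = "participant-level"
CLUSTER = "cluster-level"


class SingularDesignError(ValueError):
    """Raised when a design yields a singular information matrix."""


@dataclass(frozen=True)
class DesignParams:
    """Design constants of a two-arm parallel CRT with a binary subgroup.

    Parameters
    ----------
    m : int
        Participants per cluster (equal across clusters).
    n : int, optional
        Number of clusters.  May be left ``None`` for sample-size searches.
    pi : float
        Randomization proportion ``n1/n`` in (0, 1).
    p1 : float
        Marginal subgroup prevalence ``P[S=1]`` in (0, 1).
    sigma2 : float
        Total outcome variance conditional on subgroup and treatment.
    rho_y : float
        Outcome ICC in [0, 1), defined adjusting for the subgroup indicator.
    rho_s : float
        Subgroup-variable ICC in [0, 1].  A cluster-level subgroup variable
        forces ``rho_s = 1``.
    alpha : float
        Nominal type I error rate in (0, 1).
    subgroup_level : str
        ``"participant-level"`` or ``"cluster-level"``.
    df_offset : int
        Between-within denominator degrees of freedom are ``n - df_offset``;
        default 2, with 4 as an alternative for cluster-level subgroups.
    """

    m: int
    n: int | None = None
    pi: float = 0.5
    p1: float = 0.5
    sigma2: float = 1.0
    rho_y: float = 0.0
    rho_s: float = 0.0
    alpha: float = 0.05
    subgroup_level: str = PARTICIPANT
    df_offset: int = 2

    def __post_init__(self) -> None:
        if self.subgroup_level not in (PARTICIPANT, CLUSTER):
            raise ValueError(f"unknown subgroup_level {self.subgroup_level!r}")
        if self.subgroup_level == CLUSTER:
            object.__setattr__(self, "rho_s", 1.0)
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError("m must be a positive integer")
        if self.n is not None and not (
            isinstance(self.n, (int, np.integer)) and self.n >= 1
        ):
            raise ValueError("n must be a positive integer or None")
        for name, lo, hi in (("pi", 0.0, 1.0), ("p1", 0.0, 1.0), ("alpha", 0.0, 1.0)):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie strictly in ({lo}, {hi}); got {v}")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.rho_y < 1.0:
            raise ValueError("rho_y must lie in [0, 1)")
        if not 0.0 <= self.rho_s <= 1.0:
            raise ValueError("rho_s must lie in [0, 1]")
        if self.df_offset not in (2, 4):
            raise ValueError("df_offset must be 2 or 4")

    @property
    def p0(self) -> float:
        return 1.0 - self.p1

    @property
    def df(self) -> int:
        """Between-within denominator degrees of freedom ``n - df_offset``."""
        if self.n is None:
            raise ValueError("n is not set")
        df = self.n - self.df_offset
        if df < 1:
            raise ValueError(
                f"n={self.n} too small for df rule n-{self.df_offset}"
            )
        return df

    def with_n(self, n: int) -> "DesignParams":
        return dataclasses.replace(self, n=int(n))

    def with_m(self, m: int) -> "DesignParams":
        return dataclasses.replace(self, m=int(m))

    def with_icc(self, rho_y: float | None = None, rho_s: float | None = None) -> "DesignParams":
        kw = {}
        if rho_y is not None:
            kw["rho_y"] = rho_y
        if rho_s is not None:
            kw["rho_s"] = rho_s
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class EffectSpec:
    """Subgroup-specific treatment effects in outcome units.

    ``delta0`` is the effect in subgroup S=0 and ``delta1`` the effect in
    subgroup S=1.  The corresponding model coefficients are ``beta2 =
    delta0`` and ``beta4 = delta1 - delta0`` (treatment-by-subgroup
    interaction).
    """

    delta0: float
    delta1: float

    @property
    def beta2(self) -> float:
        return self.delta0

    @property
    def beta4(self) -> float:
        return self.delta1 - self.delta0

    def ate(self, p1: float) -> float:
        """Overall average treatment effect ``p1*delta1 + (1-p1)*delta0``."""
        return p1 * self.delta1 + (1.0 - p1) * self.delta0

    def swapped(self) -> "EffectSpec":
        return EffectSpec(self.delta1, self.delta0)

    def flipped(self) -> "EffectSpec":
        return EffectSpec(-self.delta0, -self.delta1)


@dataclass(frozen=True)
class ModelParams:
    """Full coefficient/variance-component parameterization of the outcome model."""

    effect: EffectSpec
    sigma_b2: float
    sigma_e2: float
    beta1: float = 0.0
    beta3: float = 0.15

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be >= 0")
        if not self.sigma_e2 > 0:
            raise ValueError("sigma_e2 must be > 0")

    @property
    def sigma2(self) -> float:
        return self.sigma_b2 + self.sigma_e2

    @property
    def rho_y(self) -> float:
        return self.sigma_b2 / self.sigma2

    @property
    def beta(self) -> np.ndarray:
        """Coefficient vector (beta1, beta2, beta3, beta4)."""
        return np.array(
            [self.beta1, self.effect.beta2, self.beta3, self.effect.beta4]
        )

    @classmethod
    def from_design(
        cls,
        design: DesignParams,
        effect: EffectSpec,
        beta1: float = 0.0,
        beta3: float = 0.15,
    ) -> "ModelParams":
        """Split ``design.sigma2`` into components matching ``design.rho_y``."""
        sb2 = design.rho_y * design.sigma2
        se2 = (1.0 - design.rho_y) * design.sigma2
        return cls(effect=effect, sigma_b2=sb2, sigma_e2=se2, beta1=beta1, beta3=beta3)


@dataclass(frozen=True)
class CovDelta:
    """2x2 covariance matrix of the subgroup-effect estimators (Delta0_hat, Delta1_hat)."""

    var0: float
    var1: float
    cov: float

    def __post_init__(self) -> None:
        if not (self.var0 > 0 and self.var1 > 0):
            raise ValueError("variances must be positive")
        if self.cov**2 > self.var0 * self.var1 * (1 + 1e-9):
            raise ValueError("covariance exceeds Cauchy-Schwarz bound")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.var0, self.cov], [self.cov, self.var1]])

    @property
    def corr(self) -> float:
        return self.cov / math.sqrt(self.var0 * self.var1)


def _check_core(params: DesignParams) -> None:
    if params.n is None:
        raise ValueError("DesignParams.n must be set for variance evaluation")
    denom = params.pi * (1 - params.pi) * params.p1 * params.p0 * params.n * params.m
    if denom == 0:
        raise ValueError("pi*(1-pi)*p1*p0*n*m must be nonzero")


def var_hte(params: DesignParams) -> float:
    """Variance of the interaction-effect (heterogeneity) estimator.

    For a participant-level subgroup,

        sigma2_HTE = sigma2 (1-rho_y)(1+(m-1)rho_y) /
                     [pi(1-pi) p1 p0 n m (1+(m-2)rho_y-(m-1)rho_s rho_y)],

    which for ``rho_s = 1`` (cluster-level subgroup) reduces to
    ``sigma2 (1+(m-1)rho_y) / (pi(1-pi) p1 p0 n m)``.
    """
    _check_core(params)
    m, ry, rs = params.m, params.rho_y, params.rho_s
    base = params.pi * (1 - params.pi) * params.p1 * params.p0 * params.n * m
    if rs == 1.0:
        return params.sigma2 * (1 + (m - 1) * ry) / base
    tail = 1 + (m - 2) * ry - (m - 1) * rs * ry
    if tail <= 0:
        raise ValueError("degenerate correlation structure: "
                         "1+(m-2)rho_y-(m-1)rho_s*rho_y <= 0")
    return params.sigma2 * (1 - ry) * (1 + (m - 1) * ry) / (base * tail)


def var_ate(params: DesignParams) -> float:
    """Variance of the overall-ATE estimator,
    ``sigma2 (1+(m-1)rho_y) / (pi(1-pi) n m)``.

    Identically equal to ``p1*p0`` times the cluster-level-subgroup form of
    :func:`var_hte`.
    """
    _check_core(params)
    m, ry = params.m, params.rho_y
    return (
        params.sigma2 * (1 + (m - 1) * ry) / (params.pi * (1 - params.pi) * params.n * m)
    )


def omega_delta(params: DesignParams) -> CovDelta:
    """Closed-form covariance of the pair of subgroup-effect estimators.

    ``Var(Delta0_hat) = sigma2_ATE + p1^2 sigma2_HTE``,
    ``Var(Delta1_hat) = sigma2_ATE + p0^2 sigma2_HTE``,
    ``Cov = sigma2_ATE - p1 p0 sigma2_HTE``.
    """
    sa = var_ate(params)
    sh = var_hte(params)
    p1, p0 = params.p1, params.p0
    cov = sa - p1 * p0 * sh
    if params.rho_s == 1.0 and abs(cov) < IDENTITY_TOL * max(sa, sh):
        cov = 0.0  # exact uncorrelatedness for a cluster-level subgroup
    return CovDelta(var0=sa + p1 * p1 * sh, var1=sa + p0 * p0 * sh, cov=cov)


# ---------------------------------------------------------------------------
# Exact information-matrix oracle over explicit subgroup layouts


def _delta_map() -> np.ndarray:
    # (Delta0, Delta1) = L (beta1..beta4)
    return np.array([[0.0, 1.0, 0.0, 0.0], [0.0, 1.0, 0.0, 1.0]])


def omega_delta_oracle(
    params: DesignParams,
    s_counts: Sequence[int],
    treat: Sequence[int] | None = None,
) -> CovDelta:
    """Exact GLS covariance of (Delta0_hat, Delta1_hat) for an explicit layout.

    Builds the 4x4 information matrix ``sum_i X_i' V_i^{-1} X_i`` by literal
    construction of each cluster's design matrix and compound-symmetric
    covariance, inverts it and maps to the subgroup-effect scale.  Intended
    as a verification oracle, not a user-facing calculator: the closed forms
    in :func:`omega_delta` are reproduced exactly whenever the layout's
    per-arm subgroup counts match the first two moments implied by
    ``(p1, rho_s)`` (see :func:`implied_subgroup_moments`).

    Parameters
    ----------
    s_counts : sequence of int
        Number of S=1 participants in each of the ``n`` clusters.
    treat : sequence of int, optional
        Treatment indicator per cluster; defaults to the first
        ``round(n*pi)`` clusters treated.
    """
    counts = np.asarray(s_counts, dtype=int)
    n = counts.size
    m = params.m
    if np.any(counts < 0) or np.any(counts > m):
        raise ValueError("per-cluster S=1 counts must lie in [0, m]")
    if treat is None:
        n1 = round(n * params.pi)
        treat = np.array([1] * n1 + [0] * (n - n1))
    else:
        treat = np.asarray(treat, dtype=int)
        if treat.size != n:
            raise ValueError("treat must have one entry per cluster")

    rho = params.rho_y
    vi = params.sigma2 * ((1 - rho) * np.eye(m) + rho * np.ones((m, m)))
    vinv = np.linalg.inv(vi)

    info = np.zeros((4, 4))
    for k, z in zip(counts, treat):
        s = np.zeros(m)
        s[:k] = 1.0
        x = np.column_stack([np.ones(m), np.full(m, float(z)), s, float(z) * s])
        info += x.T @ vinv @ x
    if np.linalg.matrix_rank(info) < 4 or np.linalg.cond(info) > 1e12:
        raise SingularDesignError(
            "singular information matrix: the layout does not identify all "
            "four regression coefficients (e.g. all clusters in one subgroup)"
        )
    sigma_n = np.linalg.inv(info)
    omega = _delta_map() @ sigma_n @ _delta_map().T
    return CovDelta(var0=omega[0, 0], var1=omega[1, 1], cov=omega[0, 1])


def implied_subgroup_moments(s_counts: Sequence[int], m: int) -> tuple[float, float]:
    """Return the (p1, rho_s) implied by a per-cluster S=1 count layout.

    Matches the beta-binomial moments ``E[k] = m p1`` and
    ``Var(k) = m p1 p0 (1 + (m-1) rho_s)`` against the layout's empirical
    (population) moments.  The returned ``rho_s`` can be negative when the
    layout is more balanced than binomial sampling; such layouts fall
    outside the design-parameter domain but remain valid oracle inputs.
    """
    counts = np.asarray(s_counts, dtype=float)
    p1 = counts.mean() / m
    if not 0 < p1 < 1:
        raise ValueError("layout is degenerate: all clusters in one subgroup")
    var_k = counts.var()  # population variance
    rho_s = (var_k / (m * p1 * (1 - p1)) - 1.0) / (m - 1) if m > 1 else 1.0
    return float(p1), float(rho_s)
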