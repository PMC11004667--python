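"""Random-subgroup-slope extension with Monte-Carlo variance estimation.

The base model assumes a single outcome ICC shared by all within-cluster
pairs.  Adding a random cluster-level slope on the subgroup indicator,

    Y_ij = b1 + b2*Z_i + b3*S_ij + b4*Z_i*S_ij + u_i + c_i*S_ij + e_ij,
    u_i ~ N(0, sigma_b^2),  c_i ~ N(0, sigma_c^2),

lets the within-cluster correlation differ by subgroup: pairs both in S=1
share ``sigma_b^2 + sigma_c^2`` of between-cluster variance, all other
pairs share only ``sigma_b^2``, so the model encodes three outcome ICCs.
Closed-form estimator variances are no longer tractable, so the covariance
of the subgroup-effect estimators is obtained by Monte Carlo: simulate
subgroup layouts, assemble each replicate's exact GLS information matrix,
average the information over layouts, invert the average and map to the
(Delta0_hat, Delta1_hat) scale.  Averaging on the information scale (rather
than averaging the per-layout inverses) matches the design-stage expected
information, so with a zero slope variance the procedure converges to the
closed forms without a Jensen-inequality bias.  The resulting covariance
feeds the same omnibus/intersection-union power machinery as the closed
forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design import CovDelta, DesignParams, EffectSpec, SingularDesignError
from .power import PowerResult, power_iut, power_omnibus
from .simulate import generate_subgroup, _treatment_vector

__all__ = [
    "SlopeModelParams",
    "MCVarianceResult",
    "cluster_covariance_model6",
    "mc_omega_model6",
    "power_model6",
]


@dataclass(frozen=True)
class SlopeModelParams:
    """Variance components of the random-intercept + random-subgroup-slope model."""

    sigma_b2: float
    sigma_c2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0 or self.sigma_c2 < 0:
            raise ValueError("random-effect variances must be >= 0")
        if not self.sigma_e2 > 0:
            raise ValueError("sigma_e2 must be > 0")

    @property
    def icc_s0(self) -> float:
        """Outcome ICC between two participants both in subgroup S=0."""
        return self.sigma_b2 / (self.sigma_b2 + self.sigma_e2)

    @property
    def icc_s1(self) -> float:
        """Outcome ICC between two participants both in subgroup S=1."""
        tot1 = self.sigma_b2 + self.sigma_c2 + self.sigma_e2
        return (self.sigma_b2 + self.sigma_c2) / tot1

    @property
    def icc_cross(self) -> float:
        """Outcome correlation between participants in different subgroups."""
        tot0 = self.sigma_b2 + self.sigma_e2
        tot1 = self.sigma_b2 + self.sigma_c2 + self.sigma_e2
        return self.sigma_b2 / math.sqrt(tot0 * tot1)


@dataclass(frozen=True)
class MCVarianceResult:
    """Monte-Carlo estimate of the estimator covariance with per-entry SEs."""

    omega: CovDelta
    mc_reps: int
    mc_se: np.ndarray  # 2x2 standard errors of the averaged entries
    skipped: int = 0


def cluster_covariance_model6(s: np.ndarray, params: SlopeModelParams) -> np.ndarray:
    """m x m outcome covariance of one cluster given its subgroup vector.

    ``V = sigma_e^2 I + sigma_b^2 J + sigma_c^2 s s'`` — the slope term adds
    covariance only between pairs that are both in subgroup S=1.
    """
    s = np.asarray(s, dtype=float)
    m = s.size
    return (
        params.sigma_e2 * np.eye(m)
        + params.sigma_b2 * np.ones((m, m))
        + params.sigma_c2 * np.outer(s, s)
    )


def mc_omega_model6(
    design: DesignParams,
    params: SlopeModelParams,
    mc_reps: int = 1000,
    seed: int = 0,
) -> MCVarianceResult:
    """Expected-information Monte Carlo over simulated subgroup layouts.

    Each replicate draws a full set of ``n`` cluster subgroup vectors from
    the beta-binomial generator and forms ``sum_i X_i' V_i^{-1} X_i`` with
    the three-ICC covariance.  The informations are averaged across
    replicates, the average is inverted and mapped to the subgroup-effect
    scale; per-entry Monte-Carlo standard errors come from batch means
    (batches whose own average information is singular are dropped and
    counted in ``skipped``).
    """
    if mc_reps < 1:
        raise ValueError("mc_reps must be >= 1")
    if design.n is None:
        raise ValueError("DesignParams.n must be set")
    z = _treatment_vector(design).astype(float)
    m = design.m
    lmap = np.array([[0.0, 1.0, 0.0, 0.0], [0.0, 1.0, 0.0, 1.0]])
    rng = np.random.default_rng(seed)
    infos = np.empty((mc_reps, 4, 4))
    for r in range(mc_reps):
        s_mat, _ = generate_subgroup(design, rng)
        info = np.zeros((4, 4))
        for i in range(design.n):
            s = s_mat[i].astype(float)
            v = cluster_covariance_model6(s, params)
            x = np.column_stack([np.ones(m), np.full(m, z[i]), s, z[i] * s])
            info += x.T @ np.linalg.solve(v, x)
        infos[r] = info

    def invert_to_omega(mean_info: np.ndarray) -> np.ndarray | None:
        if np.linalg.matrix_rank(mean_info) < 4 or np.linalg.cond(mean_info) > 1e12:
            return None
        return lmap @ np.linalg.inv(mean_info) @ lmap.T

    total = invert_to_omega(infos.mean(axis=0))
    if total is None:
        raise SingularDesignError(
            "average information matrix is singular: the design cannot "
            "identify both subgroup effects"
        )
    skipped = 0
    batch_omegas = []
    n_batches = min(20, mc_reps)
    for chunk in np.array_split(infos, n_batches):
        om = invert_to_omega(chunk.mean(axis=0))
        if om is None:
            skipped += 1
        else:
            batch_omegas.append(om)
    if len(batch_omegas) > 1:
        se = np.array(batch_omegas).std(axis=0, ddof=1) / math.sqrt(len(batch_omegas))
    else:
        se = np.full((2, 2), np.nan)
    omega = CovDelta(var0=total[0, 0], var1=total[1, 1], cov=total[0, 1])
    return MCVarianceResult(omega=omega, mc_reps=mc_reps, mc_se=se, skipped=skipped)


def power_model6(
    test: str,
    design: DesignParams,
    effect: EffectSpec,
    params: SlopeModelParams,
    mc_reps: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Power of the omnibus or intersection-union test under the slope model.

    Plugs the Monte-Carlo estimator covariance into the corresponding
    analytic power formula; degrees of freedom follow the same
    between-within rule as the closed-form calculators.
    """
    mc = mc_omega_model6(design, params, mc_reps=mc_reps, seed=seed)
    if test == "omnibus":
        return power_omnibus(design, effect, cov=mc.omega)
    if test == "iut":
        return power_iut(design, effect, cov=mc.omega)
    raise ValueError("test must be 'omnibus' or 'iut'")
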