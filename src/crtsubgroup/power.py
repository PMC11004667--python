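"""Power and sample-size calculators for subgroup-specific treatment effects.

Four tests are covered, all built on the closed-form covariance of the
subgroup-effect estimators (:func:`crtsubgroup.design.omega_delta`):

* **omnibus** — joint F test of H0: Delta0 = Delta1 = 0 with numerator df 2
  and between-within denominator df ``n - 2``; power is the survival
  function of a noncentral F with noncentrality
  ``lambda = (Delta0, Delta1) Omega^{-1} (Delta0, Delta1)'``.
* **iut** — intersection-union test of H0: Delta0 = 0 and/or Delta1 = 0,
  rejecting only when both standardized Wald statistics exceed
  ``t_{1-alpha}(n-2)``; power is the upper-right rectangle probability of a
  noncentral bivariate t (normal numerator shifted by the standardized
  effects, shared chi-square denominator), computed by deterministic
  quadrature.
* **interaction** — t test of the treatment-by-subgroup interaction
  ``beta4 = Delta1 - Delta0`` using the heterogeneity variance.
* **ate** — t test of the overall average treatment effect
  ``p1 Delta1 + p0 Delta0`` using the ATE variance.

The univariate t powers use the shifted-central-t convention
``P(T_{n-2} > t_{1-alpha}(n-2) - |effect|/SE)``, which reproduces the
published worked-example values; see docs/methods.md for the discussion of
this choice versus a noncentral-t formulation.

Sample sizes are found by direct search over allocation-compatible integers
(the smallest step keeping ``n*pi`` integral), as closed-form inversion is
not available.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .design import CovDelta, DesignParams, EffectSpec, omega_delta, var_ate, var_hte

__all__ = [
    "PowerResult",
    "SampleSizeResult",
    "UnreachableTargetError",
    "TESTS",
    "power",
    "power_omnibus",
    "power_iut",
    "power_interaction",
    "power_ate",
    "required_n",
    "required_m",
    "back_of_envelope_n",
    "power_grid",
    "bivariate_t_upper",
]

TESTS = ("omnibus", "iut", "interaction", "ate")

#: Absolute tolerance of the bivariate-t rectangle quadrature.
BVT_TOL = 1e-10


class UnreachableTargetError(RuntimeError):
    """Target power cannot be reached within the search cap.

    Carries the limiting power actually achievable at the cap in
    ``limiting_power``.
    """

    def __init__(self, message: str, limiting_power: float):
        super().__init__(message)
        self.limiting_power = limiting_power


@dataclass(frozen=True)
class PowerResult:
    """Outcome of a single power evaluation."""

    test: str
    power: float
    ncp: float | tuple[float, float]
    df: tuple[int, int] | int
    shape_corr: float | None = None


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size search, optionally with the design-effect comparator."""

    n_required: int
    achieved_power: float
    search_step: int
    comparator_n: int | None = None
    comparator_power: float | None = None
    relative_saving: float | None = None


# ---------------------------------------------------------------------------
# Bivariate noncentral-t rectangle probability (deterministic)


def _bvn_cdf(h: float, k: float, r: float) -> float:
    # P(X <= h, Y <= k) for standard bivariate normal with correlation r,
    # via Owen's T function (exact, deterministic).
    if abs(r) >= 1.0:
        raise ValueError("|correlation| must be < 1")
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(r) / (2 * math.pi)
    # perturb exact zeros off the removable singularity of the Owen formula
    if h == 0.0:
        h = 1e-15
    if k == 0.0:
        k = 1e-15
    rr = math.sqrt(1.0 - r * r)
    a_h = (k - r * h) / (h * rr)
    a_k = (h - r * k) / (k * rr)
    beta = 0.5 if h * k < 0 else 0.0
    phi = stats.norm.cdf
    return (
        0.5 * (phi(h) + phi(k))
        - float(special.owens_t(h, a_h))
        - float(special.owens_t(k, a_k))
        - beta
    )


def _bvn_upper(a: float, b: float, r: float) -> float:
    # P(X > a, Y > b)
    p = 1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + _bvn_cdf(a, b, r)
    return min(1.0, max(0.0, p))


def bivariate_t_upper(
    c0: float, c1: float, eta0: float, eta1: float, r: float, df: int
) -> float:
    """P(T0 > c0, T1 > c1) for a noncentral bivariate t.

    ``(T0, T1) = (Z + eta) * sqrt(df / W)`` with ``Z`` standard bivariate
    normal with correlation ``r`` and ``W ~ chi-square(df)`` shared between
    the coordinates.  Computed by adaptive quadrature of the chi-square
    mixture over an exact bivariate-normal rectangle; deterministic, with
    absolute tolerance ``BVT_TOL``.
    """
    if df < 1:
        raise ValueError("df must be >= 1")

    def integrand(w: float) -> float:
        s = math.sqrt(w / df)
        return stats.chi2.pdf(w, df) * _bvn_upper(c0 * s - eta0, c1 * s - eta1, r)

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=BVT_TOL, epsrel=1e-10, limit=300
    )
    return min(1.0, max(0.0, val))


# ---------------------------------------------------------------------------
# Power calculators


def power_omnibus(
    params: DesignParams,
    effect: EffectSpec,
    cov: CovDelta | None = None,
) -> PowerResult:
    """Noncentral-F power of the omnibus test of both subgroup effects.

    ``cov`` may supply a precomputed estimator covariance (used by the
    random-slope extension); by default the closed form is used.
    """
    nu = params.df
    cov = omega_delta(params) if cov is None else cov
    d = np.array([effect.delta0, effect.delta1])
    try:
        lam = float(d @ np.linalg.solve(cov.matrix, d))
    except np.linalg.LinAlgError as exc:
        raise ValueError("estimator covariance is singular") from exc
    if lam < 0:
        raise ValueError("estimator covariance is not positive definite")
    crit = stats.f.ppf(1 - params.alpha, 2, nu)
    if lam == 0.0:
        pw = float(stats.f.sf(crit, 2, nu))
    else:
        pw = float(stats.ncf.sf(crit, 2, nu, lam))
    return PowerResult(test="omnibus", power=pw, ncp=lam, df=(2, nu))


def power_iut(
    params: DesignParams,
    effect: EffectSpec,
    cov: CovDelta | None = None,
    flip_signs: bool = False,
) -> PowerResult:
    """Bivariate-t power of the intersection-union test.

    Rejection requires both standardized effects to exceed
    ``t_{1-alpha}(n-2)``; effects must be on the beneficial (positive)
    side.  ``flip_signs=True`` negates both effects first, for outcomes
    where benefit is a decrease.
    """
    nu = params.df
    if flip_signs:
        effect = effect.flipped()
    if effect.delta0 <= 0 or effect.delta1 <= 0:
        raise ValueError(
            "intersection-union power requires Delta0 > 0 and Delta1 > 0 under "
            "the one-sided upper-tail convention; negate both effects "
            "(flip_signs=True) if benefit is negative"
        )
    cov = omega_delta(params) if cov is None else cov
    eta0 = effect.delta0 / math.sqrt(cov.var0)
    eta1 = effect.delta1 / math.sqrt(cov.var1)
    r = cov.corr
    if abs(r) >= 1:
        raise ValueError("|shape correlation| must be < 1")
    c = float(stats.t.ppf(1 - params.alpha, nu))
    pw = bivariate_t_upper(c, c, eta0, eta1, r, nu)
    return PowerResult(
        test="iut", power=pw, ncp=(eta0, eta1), df=nu, shape_corr=r
    )


def _shifted_t_power(ncp: float, nu: int, alpha: float) -> float:
    # one-sided power on the absolute standardized effect:
    # P(T_nu > t_{1-alpha}(nu) - |ncp|)
    crit = stats.t.ppf(1 - alpha, nu)
    return float(stats.t.sf(crit - abs(ncp), nu))


def power_interaction(params: DesignParams, effect: EffectSpec) -> PowerResult:
    """Power of the treatment-by-subgroup interaction test.

    Standardizes ``|Delta1 - Delta0|`` by the heterogeneity standard error
    (square root of the interaction-estimator variance) with df ``n - 2``.
    Returns ``alpha`` when the two subgroup effects coincide.
    """
    nu = params.df
    ncp = effect.beta4 / math.sqrt(var_hte(params))
    pw = _shifted_t_power(ncp, nu, params.alpha)
    return PowerResult(test="interaction", power=pw, ncp=ncp, df=nu)


def power_ate(params: DesignParams, effect: EffectSpec) -> PowerResult:
    """Power of the overall-average-treatment-effect test.

    Standardizes ``|p1 Delta1 + p0 Delta0|`` by the ATE standard error with
    df ``n - 2``.  Returns ``alpha`` when the ATE is zero.
    """
    nu = params.df
    ncp = effect.ate(params.p1) / math.sqrt(var_ate(params))
    pw = _shifted_t_power(ncp, nu, params.alpha)
    return PowerResult(test="ate", power=pw, ncp=ncp, df=nu)


_POWER_FUNCS = {
    "omnibus": power_omnibus,
    "iut": power_iut,
    "interaction": power_interaction,
    "ate": power_ate,
}


def power(test: str, params: DesignParams, effect: EffectSpec) -> PowerResult:
    """Dispatch to the power calculator for ``test`` (one of ``TESTS``)."""
    if test not in _POWER_FUNCS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    return _POWER_FUNCS[test](params, effect)


# ---------------------------------------------------------------------------
# Sample-size searches


def allocation_step(pi: float) -> int:
    """Smallest positive integer step keeping ``n*pi`` integral."""
    return Fraction(pi).limit_denominator(10**6).denominator


def _start_n(params: DesignParams, step: int) -> int:
    n = step
    while n - params.df_offset < 1:
        n += step
    return n


def required_n(
    test: str,
    params: DesignParams,
    effect: EffectSpec,
    target_power: float = 0.8,
    n_cap: int = 10_000,
) -> SampleSizeResult:
    """Smallest allocation-compatible number of clusters reaching ``target_power``.

    Scans ``n`` upward from the smallest admissible value in steps that keep
    the arm allocation integral (step 2 for ``pi = 1/2``) and returns the
    first crossing.  Raises :class:`UnreachableTargetError` if the target is
    not reached by ``n_cap``.
    """
    if not params.alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    step = allocation_step(params.pi)
    n = _start_n(params, step)
    last = 0.0
    while n <= n_cap:
        pw = power(test, params.with_n(n), effect).power
        if pw >= target_power:
            return SampleSizeResult(n_required=n, achieved_power=pw, search_step=step)
        last = pw
        n += step
    raise UnreachableTargetError(
        f"{test}: power {last:.4f} at n={n_cap} below target {target_power}",
        limiting_power=last,
    )


def required_m(
    test: str,
    params: DesignParams,
    effect: EffectSpec,
    target_power: float = 0.8,
    m_cap: int = 10_000,
) -> SampleSizeResult:
    """Smallest cluster size reaching ``target_power`` at fixed ``n``.

    Power can plateau in ``m`` (the design-effect ceiling); if the target is
    unreachable the raised :class:`UnreachableTargetError` reports the
    limiting power at the cap.
    """
    if not params.alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    if params.n is None:
        raise ValueError("required_m needs DesignParams.n")
    ceiling = power(test, params.with_m(m_cap), effect).power
    if ceiling < target_power:
        raise UnreachableTargetError(
            f"{test}: power plateaus at {ceiling:.4f} (m={m_cap}) below target "
            f"{target_power}",
            limiting_power=ceiling,
        )
    for m in range(1, m_cap + 1):
        pw = power(test, params.with_m(m), effect).power
        if pw >= target_power:
            return SampleSizeResult(n_required=m, achieved_power=pw, search_step=1)
    raise AssertionError("unreachable")  # pragma: no cover


def back_of_envelope_n(
    test: str,
    params: DesignParams,
    effect: EffectSpec,
    target_power: float = 0.8,
    n_cap: int = 10_000,
) -> SampleSizeResult:
    """Design-effect comparator alongside the exact search.

    The comparator first sizes the trial ignoring all intracluster
    correlation (``rho_y = rho_s = 0``), then inflates by the conventional
    design effect ``1 + (m-1) rho_y`` and rounds up to the next
    allocation-compatible integer ``n_c``.  The returned result carries the
    exact search in ``n_required``/``achieved_power``, the comparator size
    and its actual power (evaluated with the true ICCs) in
    ``comparator_n``/``comparator_power``, and the relative saving
    ``(n_c - n)/n_c * 100`` in percent.
    """
    exact = required_n(test, params, effect, target_power, n_cap)
    iid = required_n(
        test, params.with_icc(rho_y=0.0, rho_s=0.0), effect, target_power, n_cap
    )
    step = allocation_step(params.pi)
    de = 1 + (params.m - 1) * params.rho_y
    n_c = int(math.ceil(iid.n_required * de / step - 1e-9) * step)
    actual = power(test, params.with_n(n_c), effect).power
    saving = (n_c - exact.n_required) / n_c * 100.0
    return SampleSizeResult(
        n_required=exact.n_required,
        achieved_power=exact.achieved_power,
        search_step=step,
        comparator_n=n_c,
        comparator_power=actual,
        relative_saving=saving,
    )


# ---------------------------------------------------------------------------
# Grids


def power_grid(
    test: str,
    params: DesignParams,
    effect: EffectSpec,
    rho_y: Iterable[float] | None = None,
    rho_s: Iterable[float] | None = None,
    m: Iterable[int] | None = None,
    p1: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Evaluate power over a cartesian grid of sensitivity axes.

    Axes default to the single value in ``params``.  Cells whose parameter
    combination is invalid are recorded with ``NaN`` power rather than
    aborting the grid.
    """
    ry_ax = list(rho_y) if rho_y is not None else [params.rho_y]
    rs_ax = list(rho_s) if rho_s is not None else [params.rho_s]
    m_ax = list(m) if m is not None else [params.m]
    p1_ax = list(p1) if p1 is not None else [params.p1]
    rows = []
    for ry, rs, mm, pp1 in product(ry_ax, rs_ax, m_ax, p1_ax):
        row = {
            "test": test,
            "n": params.n,
            "m": mm,
            "pi": params.pi,
            "rho_y": ry,
            "rho_s": rs,
            "p1": pp1,
            "delta0": effect.delta0,
            "delta1": effect.delta1,
        }
        try:
            pt = dataclasses.replace(params, m=int(mm), rho_y=ry, rho_s=rs, p1=pp1)
            row["power"] = power(test, pt, effect).power
        except (ValueError, UnreachableTargetError):
            row["power"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
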