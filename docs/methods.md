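# Methods

This note documents the statistical machinery behind `crtsubgroup`: the
model, the power formulas and their numerical implementation, the
simulation harness used to validate them, and the design choices made where
more than one convention was defensible.

## Model and estimands

The package targets two-arm parallel cluster-randomized trials (CRTs) with
`n` clusters of equal size `m`, randomization proportion `π = n1/n`, a
continuous outcome and a binary subgroup variable `S` measured at the
participant level (or at the cluster level as a special case). The analysis
model is the linear mixed ANCOVA with a random cluster intercept:

    Y_ij = β1 + β2 Z_i + β3 S_ij + β4 Z_i S_ij + b_i + ε_ij,
    b_i ~ N(0, σ_b²),   ε_ij ~ N(0, σ_ε²).

The estimands are the subgroup-specific treatment effects `Δ0 = β2` and
`Δ1 = β2 + β4`. Two intracluster correlations govern their precision: the
outcome ICC `ρ_y = σ_b²/(σ_b² + σ_ε²)`, defined **conditional on subgroup
and treatment** (the total variance σ² in all formulas is likewise the
conditional outcome variance — the model has no other variance, so the two
notations used for it are the same quantity), and the subgroup-variable ICC
`ρ_s`, the within-cluster correlation of `S`. A cluster-level subgroup
variable is the `ρ_s = 1` boundary.

`design.omega_delta` implements the closed-form 2×2 covariance of
`(Δ̂0, Δ̂1)` as weighted combinations of the ATE variance and the
heterogeneity (interaction) variance; the identities
`σ²_ATE = p1 p0 σ̃²_HTE`, the `ρ_s = 1` uncorrelatedness of the two
estimators, and the monotonicity of `σ²_HTE` in `ρ_s` are enforced as
property tests. An exact oracle (`omega_delta_oracle`) builds
`Σ X_i' V_i⁻¹ X_i` literally for an explicit per-cluster subgroup layout and
inverts it. Because each cluster's information depends on its S=1 count `k`
only linearly and quadratically, a deterministic layout reproduces the
closed form exactly when the per-arm first two moments of `k` match the
beta-binomial moments `E[k] = m p1`, `Var(k) = m p1 p0 (1+(m−1)ρ_s)`; the
helper `implied_subgroup_moments` inverts this relation, and oracle tests
construct integer layouts and derive the `(p1, ρ_s)` they represent.

## Power formulas and numerical conventions

**Omnibus test.** `F* = (Δ̂0,Δ̂1) Ω̂⁻¹ (Δ̂0,Δ̂1)ᵀ / 2` is referred to
`F(2, n−2)`; under the alternative the power is the noncentral-F survival
function with noncentrality `λ = (Δ0,Δ1) Ω⁻¹ (Δ0,Δ1)ᵀ` (the full quadratic
form — the ÷2 belongs to the statistic, not to λ). The `λ = 0` case is
special-cased to return exactly α. The between-within denominator df
`n − 2` is the default; `n − 4` is available for cluster-level subgroup
variables.

**Intersection–union test.** Rejects only when both standardized Wald
statistics exceed `t_{1−α}(n−2)` — a deliberately simple, at-most-
conservative critical-value choice on the composite null. Power is the
upper-right rectangle probability of a **noncentral bivariate t**:
`(T0, T1) = (Z + η) √(ν/W)` with `Z` bivariate normal (correlation from the
estimator covariance), shared `W ~ χ²_ν`, `ν = n − 2`, and standardized
effects `η_k = Δ_k/√Var(Δ̂_k)` (the √n factors in the statistic and its
standard error cancel, since the Result-1 variances already scale as 1/n).
Two candidate conventions exist here — a location-*shifted* central
bivariate t versus the genuinely noncentral one. They differ at small df
(0.804 vs 0.806 at ν = 32 for the worked example), and only the noncentral
form reproduces the published design values, so it is the implemented
convention — it is also what R's `mvtnorm::pmvt(delta=…)` computes.
Numerically the probability is an adaptive quadrature of the χ² mixture
over an exact Owen's-T-based bivariate-normal rectangle: deterministic, no
Monte-Carlo integration, absolute tolerance 1e−10 (a seeded large-sample MC
oracle cross-checks it in the tests). Effects must be on the positive side;
`flip_signs=True` negates both for outcomes where benefit is a decrease.

**Interaction and ATE companion tests.** Both are univariate t
calculations: the interaction effect `|Δ1 − Δ0|` standardized by
`σ_HTE`, and the ATE `|p1 Δ1 + p0 Δ0|` standardized by `σ_ATE`, with df
`n − 2`. The implemented power convention is the one-sided shifted central
t, `P(T_ν > t_{1−α}(ν) − |effect|/SE)`, which returns α exactly at a null
effect. Among the candidate conventions (two-sided noncentral t, two-sided
F, one-sided noncentral t, one-sided shifted t) only the last reproduces
the published worked-example values at both large df (284 clusters) and
small df (12 clusters), so it is the package's convention; users who want a
strictly two-sided calculation can halve α.

**Sample-size search.** No closed-form inversion exists, so `required_n`
scans upward over allocation-compatible integers — the step is the smallest
integer keeping `n·π` integral (2 for π = 1/2), starting at the smallest n
admissible under the df rule — and returns the first crossing, which is the
minimal crossing whenever power is nondecreasing in n (verified on every
reproduced scenario). `required_m` mirrors the search over cluster size and
must handle the design-effect ceiling: power can plateau below the target
as m → ∞, in which case an `UnreachableTargetError` reports the limiting
power. The back-of-the-envelope comparator sizes the trial with both ICCs
zero, multiplies by `1+(m−1)ρ_y`, and rounds **up** to the next
allocation-compatible integer; its actual power is then evaluated with the
true ICCs. This rounding convention reproduces every published comparator
value.

## Simulation harness

The harness follows the standard aims / data-generating-mechanisms /
estimands / methods / performance-measures structure. Subgroup indicators
are beta-binomial: `p_i ~ Beta(q1, q2)`, `S_ij ~ Bernoulli(p_i)` with
`q1 = p1(1/ρ_s − 1)`, `q2 = p0(1/ρ_s − 1)`, so the marginal prevalence is
p1 and the subgroup ICC is `ρ_s = (1+q1+q2)⁻¹`; `ρ_s = 0` and `ρ_s = 1`
take exact iid and cluster-level paths. Outcomes add Gaussian cluster
intercepts and residuals to the linear predictor with `σ_b² = ρ_y σ²`.
Nuisance coefficients default to `β1 = 0`, `β3 = 0.15`; they do not affect
power, and a test verifies this empirically. Null scenarios set
`β2 = β4 = 0` for the omnibus test but only `β2 = 0` for the IUT (the
boundary of its composite null retains the interaction).

Each replicate is fitted by **maximum likelihood** (not REML, matching the
validated tables). The fitter exploits the equal-cluster-size
compound-symmetry structure: for a candidate outcome ICC the GLS
coefficients and the ML variance scale are closed-form functions of
per-cluster sufficient statistics, so the full ML fit is a one-dimensional
bounded maximization over the ICC (floored at 0, capped at 0.999, scalar
tolerance 1e−8), costing well under a millisecond per dataset. A unit test
verifies agreement with statsmodels' `MixedLM(reml=False)` to 1e−5 on
coefficients and variance components. The estimator covariance `Ω̂` plugs
the estimated components and the realized design into the
information-matrix inverse — the same `Σ_n` formula as the closed forms.
Rank-deficient replicates are recorded as non-converged and dropped from
the denominator with the convergence rate reported (a warning fires below
95%).

Reproducibility: one master seed per scenario, with independent per-replicate
child streams, so results are bit-identical across runs and scenarios could
be parallelized without changing them. The validation bands are the
published ones — empirical size in [0.040, 0.060] and |empirical −
predicted power| ≤ 0.020 at 2000 replicates — with 3 binomial Monte-Carlo
standard errors used at reduced replication counts. The default test suite
runs one full 2000-replicate scenario (a few seconds with this fitter) and
several 400–1500-replicate checks; `reproduce-tables` regenerates all 54
scenarios' deterministic columns in ~80 s and accepts a `--reps` flag for
the empirical columns.

What the generator does *not* emulate: variable cluster sizes, attrition,
non-Gaussian outcomes, covariate adjustment beyond the subgroup, or
misspecified correlation structures. Passing tests therefore certify the
internal consistency of formulas and fitting under the assumed model, not
robustness to real-data violations of it.

## Random-subgroup-slope extension

Adding a cluster-level random slope `c_i S_ij` with `c_i ~ N(0, σ_c²)`
yields three outcome ICCs (within-S0 pairs, cross-subgroup pairs,
within-S1 pairs); pairs both in S=1 share the extra `σ_c²`. Closed-form
estimator variances are intractable here, so `mc_omega_model6` simulates
subgroup layouts, forms each replicate's exact information
`Σ X_i' V_i⁻¹ X_i` with `V_i = σ_ε²I + σ_b²J + σ_c² s sᵀ`, **averages the
information matrices**, inverts the average and maps to the
`(Δ̂0, Δ̂1)` scale; Monte-Carlo standard errors come from batch means
(20 batches). Averaging on the information scale rather than averaging
per-layout inverses is deliberate: the per-cluster information is linear in
`k` and `k²`, so the mean information converges to the design-stage
expected information and the procedure recovers the closed forms exactly as
`σ_c² → 0`, whereas averaging inverses carries a Jensen-inequality bias
(measured at ~2% for n = 16, m = 8) that would never vanish. The companion
web-appendix procedure this module reconstructs is summarized rather than
printed in the source material, so the reconstruction is documented as such;
its two testable anchors — closed-form recovery at `σ_c² = 0` and variance
inflation confined to the exposed subgroup — both hold. Default
`mc_reps = 1000` with a required seed.

## Interfaces and defaults

`DesignParams` validates all domains (proportions strictly interior,
`ρ_y ∈ [0,1)`, `ρ_s ∈ [0,1]`, cluster-level subgroup forcing `ρ_s = 1`);
`n·π` integrality is enforced where data are generated or searches stepped,
not for pure formula evaluation. Default search cap is 10,000 clusters.
CSV output rounds powers to 3 decimals and savings to 1 (matching the
published precision); JSON retains full precision. The CLI validates config
files against the known option set and rejects unknown keys; `--save-config`
writes the resolved parameter set so any run can be replayed exactly.

## Known limitations

Equal cluster sizes only; one binary subgroup variable (no multi-level or
multiple moderators); no small-sample df corrections beyond the
between-within rule (scenarios with very few clusters, n ≤ 12, are outside
the validated range); no binary/categorical outcomes; no random treatment
slope. The IUT critical-value choice `c0 = c1 = t_{1−α}(n−2)` is
conservative on the composite null, markedly so for small cluster sizes —
the validation tables show empirical sizes near 2–3% at m = 20 — which is a
property of the test, not an implementation artifact.
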