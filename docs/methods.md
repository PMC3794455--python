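# Methods

## Model family

All models concern a pair of repeated continuous measurements `(Y1, Y2)` on the
same subjects, assumed bivariate normal. A model is a map `θ ↦ (μ(θ), Σ(θ))`
from at most five free parameters to the implied mean vector and 2×2 covariance
of the pair; five is the saturated count (two means, two variances, one
covariance), so `df = 5 − #free ≥ 0`.

The latent change score `LCS21` is defined by fixing the regression of `Y2` on
`Y1` and on `LCS21` both to 1, the `Y2` intercept to 0, and the `Y2` residual to
0, so the latent variable *is* `Y2 − Y1`. The implied structures:

- **correlated**: `μ = (μ1, μ1+μΔ)`, `Σ = [[σ1², σ1²+σ1Δ], [σ1²+σ1Δ, σ1²+σΔ²+2σ1Δ]]`.
- **SF/M** (`b = 1+γ`): `μ = (μ1, α+b·μ1)`, `Σ = [[σ1², b·σ1²], [b·σ1², b²σ1²+ψ]]`.
- **no-SF/M**: SF/M with `γ` fixed at 0 (one df).
- **lagged AR**: identical algebra with `β` in place of `b` — the same model as
  SF/M in different coordinates, which the engine's reparameterization-invariance
  tests exploit (`F_min`, χ² and all implied moments agree to machine precision;
  `β̂ = 1 + γ̂` exactly).

## Estimation

The discrepancy minimized is the normal-theory ML fit function with mean
structure,

    F(θ) = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − 2 + (m̄−μ(θ))ᵀ Σ(θ)⁻¹ (m̄−μ(θ)),

where `m̄` and `S` are the sample mean vector and covariance matrix. `F ≥ 0`
with equality iff the implied moments equal the sample moments, so every
saturated specification fits perfectly and its estimates are the closed-form
moment solutions.

Three conventions interlock, and are chosen so that the saturated mean-change
standard error coincides with the classical paired-test standard error
`s_D/√n` (both are exposed as flags):

1. **Moment denominator** `n−1` (unbiased) by default; `n` available for
   pure-ML comparisons.
2. **χ² scale** `(n−1)·F_min` by default (the convention of the classical SEM
   packages); `n·F_min` behind a flag. The γ = 0 likelihood-ratio χ² has the
   closed form `−scale·ln(1−r²)`, `r` = sample correlation of baseline and
   change, which serves as the engine's independent oracle.
3. **Standard errors** from the observed information of the Gaussian
   log-likelihood `−(n/2)·F` evaluated at the optimum. With the `n−1` moment
   convention this yields `SE(μ̂Δ) = √(s_D²/n)` for the correlated model and
   `SE(α̂) = √(ψ̂/n)` with `ψ̂ = s_D²(1−r²)` for the SF/M model at a centered
   baseline (no extra n−2 small-sample correction — the residual variance is
   deliberately kept on the same `n−1`-moment scale as the correlated model so
   the two SEs are comparable).

**Numerics.** Free variances are log-transformed during the search so they stay
positive; the optimizer is L-BFGS-B with *exact* gradients obtained by
complex-step differentiation through the 2×2 closed forms (step 1e−20), started
from the closed-form moment solutions (which, for every spec shipped here, are
already the optimum — the search then merely verifies stationarity; a dedicated
test confirms the optimizer also recovers the optimum from deliberately
perturbed starts). Up to five restarts with jittered starts use fixed sub-seeds
derived from the model name. A point worse than the analytic start is never
accepted. The Hessian for standard errors is a central difference of the
complex-step gradient (relative step 1e−6) in the original parameterization,
accurate to ≈1e−9 relative — comfortably inside the 1e−8 agreement the
equivalence suite demands. Implied covariances outside the positive-definite
region during search receive a large penalty value rather than an exception;
`F_min` within −1e−8 of zero is clamped to 0. Degenerate inputs (zero wave
variance, zero change-score variance, `|ρ| ≥ 1` in summary input) raise typed
errors before any fit starts.

**Significance conventions.** Critical ratios (estimate/SE) are referred to the
standard normal, two-sided — the SEM convention, and exactly what makes the
structural p differ from the classical *t* p at the same ratio. The classical
test uses *t* with `n−1` df. The SF/M significance test is the intercept Wald
test; the γ = 0 likelihood-ratio test is available separately via the nested
χ²-difference machinery (the two answer different questions: "is the adjusted
mean change zero" vs. "is change related to baseline"). The χ²-difference
verdict field is advisory text at a configurable α (default 0.05) and never
gates computation.

**Centering.** All raw-data analyses center both waves on the baseline mean by
default. This changes only the means (differences, variances, covariances and ρ
are invariant, which a property test asserts to 1e−12), and makes the SF/M
intercept interpretable as the mean change at the average baseline — without it
the intercept refers to baseline = 0 and a warning is issued.

## Sensitivity sweep over an assumed correlation

Given published `n`, per-wave means and SDs but no paired correlation, the sweep
rebuilds the moments at each ρ on a grid (default 0.00–0.95, step 0.05 — a grid
fine enough to bracket a threshold to one band of 0.05), runs the classical test
and the SF/M intercept test, and refines each significance threshold ρ* by
bisection between the bracketing grid points to |Δρ| < 1e−4, using the
closed forms of the two saturated tests (`var_D = sd1²+sd2²−2ρ·sd1·sd2`;
`ψ = sd2²(1−ρ²)` at a centered baseline). For equal SDs the classical threshold
has the closed form `ρ* = 1 − n(d/t_crit)²/(2·sd²)`, the sweep's acceptance
oracle. Since `ψ ≤ var_D` always and the normal reference is lighter-tailed than
*t*, the SF/M p-value is pointwise ≤ the classical one and its threshold is
never larger. The external study that motivates this design prints no usable
means or SDs, so the module ships a synthetic worked design of the same shape
(n = 24, mean change −0.3, unit SDs) rather than bundling unverifiable numbers.

## Synthetic data

The generator draws i.i.d. bivariate-normal pairs via the Cholesky factor of the
2×2 covariance, one PCG64 substream per replication keyed by
`SeedSequence([seed, rep_index])` — bit-reproducible and order-independent, so
studies can parallelize without changing results; the generator algorithm is
recorded in study outputs. Defaults emulate HgA1c-style data: a clinical scale
around 7.5%, per-wave SD ≈ 1.3, test–retest correlation ≈ 0.57, and (for
alternative-hypothesis designs) a small negative mean change. What the generator
deliberately does *not* emulate: skewness and heavy tails, floor/ceiling
effects, measurement error distinct from occasion-specific variance, or dropout
— so passing tests certify the algebra and calibration under normality, not
robustness to real-data pathologies.

Monte-Carlo studies use the closed forms of the saturated tests per replication
(their exact agreement with the numeric engine is itself a tested property);
the equivalence study fits the engine deliberately, since the engine is what it
audits. Problem sizes in the shipped studies — 200 datasets for the equivalence
suite, 1000 replications at n = 500 for parameter recovery, 5000 null
replications at n = 100 for type-I calibration — were chosen to make the
Monte-Carlo error small against each check's tolerance (e.g. the 3σ binomial
band at 5000 replications is ±0.9 points around the 5% nominal rate).

## Known limitations

- Two variables, two waves only; no covariates, groups, mixtures or FIML
  missing-data handling (rows with missing values are dropped with a logged
  count).
- Normal-theory ML only; no robust or weighted least-squares estimators, no
  bootstrap SEs.
- The "|γ| equals one minus stability" reading holds exactly in unstandardized
  form (`γ = β − 1`) and, against the *standardized* stability (= ρ), only when
  the two wave SDs are equal; the package asserts the unstandardized identity
  and reports standardized stability separately.
- The sensitivity sweep treats the assumed ρ as exact; it propagates no
  uncertainty in the published means/SDs themselves.
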