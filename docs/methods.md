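# Methods

## Model

Ratings `Y[r,t,i,j]` (rater *r*, target *t*, indicator/task-object *i*,
construct *j*) are decomposed within classical test theory into a true
score and measurement error, and the true score into orthogonal latent
components. One indicator per construct (the first, by convention the most
established task object) is the **reference indicator**; its loadings are
all fixed to 1, which identifies the latent metrics while leaving every
latent variance free. Non-reference indicators carry free loadings on the
trait, rater and interaction variables plus a target-level object-method
residual `OM[t,i,j]`.

* **DTCC** (cross-classified): target traits `T` (covariance `Sigma_T`,
  J×J), object-method effects `OM` (covariance `Sigma_OM` over all
  non-reference (i, j) pairs), rater effects `R[r,j]` and rater–target
  interactions `INT[r,t,j]` with per-construct variances. Cross-construct
  rater and interaction covariances exist only when the same raters score
  both constructs; with disjoint panels those effects are orthogonalized
  (the package flags estimability from the observed design).
* **DTTL** (two-level simplification): `R` and `INT` conglomerated into a
  unique method effect `UM[r,t,j]`; this is an ordinary two-level SEM and
  is the only variant with a known marginal ML estimator.

All scores are treated as continuous Gaussian. A Likert discretization
(round + clamp) exists in the simulator as a robustness device only.

## Preprocessing

Idea-level ratings are collapsed per (target, rater, task) cell with the
0.75 quantile of the idea-rating distribution (robust against low-quality
outlier ideas of otherwise creative targets). The quantile convention
defaults to linear interpolation between order statistics (position
`q·(n−1)+1`); nearest-rank, Weibull ("exclusive") and median-unbiased
conventions are selectable, because reproducing scores computed by other
software may require matching its convention. Scale bounds are metadata
only — aggregated scores are never truncated.

Classical agreement is summarised by the two-way random-effects,
absolute-agreement, average-measure ICC(A,k) with the McGraw–Wong F-based
confidence interval (Satterthwaite df for the single-measure coefficient,
Spearman–Brown step-up). Under missingness the ICC uses complete-case
targets per construct; the study design has no within-construct
missingness, so this choice is inert there.

## Gibbs sampler

All full conditionals are conjugate. One sweep draws: the joint target
block `(T_t, OM_t)` per target (multivariate normal; the posterior
precision is shared by all targets in a balanced design and is assembled
once per sweep); rater effects; interaction/unique-method effects; per
indicator the intercept and free loadings jointly (normal); an extra joint
(intercepts, rater effects) block for the DTCC — with 3–4 raters the rater
mean and the intercepts are nearly collinear, and without this block the
chains need an order of magnitude more iterations; residual and method
variances (inverse-gamma); `Sigma_T` and `Sigma_OM` (inverse-Wishart).

**Priors** (all overridable via `PriorSpec`): normal(0, 1e6) for
intercepts and loadings; inverse-gamma(0.001, 0.001) for scalar variances;
for covariance matrices the *flat improper* inverse-Wishart
(df = −(dim+1), zero scale), the default of mainstream Bayesian SEM
software. A proper identity-scale inverse-Wishart is available but not
default: it is only weakly informative when latent variances are near 1,
and for rating data whose object-method covariance is nearly singular
(smallest eigenvalue ~1e−3 in the shipped estimates) the identity scale
dominates the smallest eigendirections, displaces the posterior from the
likelihood's ridge, and visibly distorts posterior predictive checks. The
flat prior requires more targets than about twice the covariance block
dimension; all supported designs satisfy this easily.

**Convergence.** The Gelman–Rubin potential scale reduction factor
`PSR = sqrt(((n−1)/n·W + B/n)/W)` is monitored for every model parameter
(never for latent effects, whose number grows with the data), computed
from the retained second halves of the chains. Auto mode doubles the total
chain length and re-checks until max PSR < 1.1 (or the iteration cap);
fixed mode runs a preset length. Burn-in is the first half. All-constant
equal chains define PSR = 1; constant unequal chains define +inf.
Non-convergence is returned flagged, never silently.

**Parameter fixing.** `McmcConfig.fix` holds named parameters constant
while the rest are drawn from their full conditionals — used by the test
suite to reduce the sampler to a one-parameter conjugate sub-model whose
posterior is computable by quadrature.

## Posterior predictive check

For a subsample of retained draws θ_d the discrepancy

```
chi2(Y; θ) = 2 [ sup loglik_saturated(Y) − loglik_twolevel(Y; moments(θ)) ]
```

is evaluated for the observed data and for a replicated dataset of
identical design simulated from θ_d; reported are the mean and central 95%
interval of Δχ² = observed − replicated and the posterior predictive
p-value (fraction of replications with replicated ≥ observed). The model is
maintained when the interval covers 0 and ppp > .05.

The discrepancy functional is the balanced two-level Gaussian
likelihood-ratio in the data's sufficient statistics: pooled within-target
covariances per construct and the covariance of the per-target rater
means. For the DTTL this equals the exact marginal likelihood ratio. For
the DTCC it is a *moment* discrepancy: the within matrices include the
rater-effect contribution (rater disagreement appears in the within-target
scatter), while the between matrices exclude it (rater means are shared by
all targets and cancel from between-target deviations). Observed and
replicated data are always scored identically, which is what calibration
requires. Limitation: with very small rater panels the realized
rater-variance fluctuates strongly across replications, so the DTCC check
has wide Δχ² intervals and little power against rater-level
misspecification; its target-level power is unaffected.

## Two-level maximum likelihood

For balanced construct-blocked designs the DTTL marginal likelihood
factors exactly into a within part (pooled within-target scatter, Wishart
with `G(k_j−1)` df and covariance `Sigma_W_j`) and a between part (target
mean vectors, iid normal with covariance `Psi = Sigma_B +
blockdiag(Sigma_W_j / k_j)`). Both parts are closed-form in the sufficient
statistics, so one likelihood evaluation costs microseconds. Genuinely
unbalanced data are not supported by this engine (rows must be completed
or dropped upstream); the construct-blocked missingness of the study
design is handled exactly.

Optimization is quasi-Newton (L-BFGS-B, finite-difference gradients, one
restart from the solution) on an unconstrained reparameterization: log
residual/method variances and Cholesky factors with log-diagonals for
`Sigma_T` and `Sigma_OM`. Every iterate is a valid parameter point;
Heywood paths appear as variances driven to the zero boundary and are
clamped with a warning. Starting values are method-of-moments: within
blocks via the tetrad `s12·s13/s23` for the unique-method variance,
between blocks by regressing on the reference indicators and projecting
the residual matrix to the PSD cone.

The saturated model is the unrestricted two-level mean + covariance model;
for balanced designs its supremum is closed-form (within suprema at the
pooled within matrices, between supremum at the ML covariance of target
means). `chi2 = 2(loglik_sat − loglik_model)`.

**Degrees of freedom and effective df.** `dttl_degrees_of_freedom` uses
the standard two-level SEM counting convention: `p` means plus a full
`p(p+1)/2` covariance block at *each* level, minus free parameters — 13
for the 2×3 study design. Under construct-blocked missingness, however,
the 9 cross-construct within-level covariances are never observed (no
rater scores both constructs) and each construct's within-level one-factor
block is just-identified, so the LR statistic's asymptotic distribution has
only 4 effective degrees of freedom — the proportionality constraints tying
the trait loadings to both reference indicators. Simulation confirms this:
the mean exact-fit χ² over model-true replications sits near 4.6, not near
the conventional 13. The conventional df is reported because it is what
reference software prints (and what the p-value of that software refers
to); users comparing the χ² mean to df should use the effective count.

**Fit indices.** `RMSEA = sqrt(max(chi2 − df, 0)/(df·N))` with `N` the
total number of rater–target rows (this is the convention that reproduces
published multilevel values; with the 2×3 design, χ² = 207.954, df = 13 and
N = 1414 give 0.103). SRMR per level is the root mean square of covariance
residuals standardized by the observed standard deviations at that level,
over all unique elements including the diagonal; the between-level
observed matrix is the target-mean covariance minus the model's
within/k contribution. Cut-offs: reject on p(χ²) < .05; RMSEA/SRMR good
≤ .05, acceptable ≤ .08 (inclusive); conflicting statistics are reported
as conflicts, not averaged.

Standard errors default to the observed information (finite-difference
Hessian in the natural parameterization); a Huber–White cluster sandwich
over targets is optional. Point estimates and fit statistics are the
comparison surface; SEs are secondary.

## Variance decomposition

Closed-form per indicator from the absolute components
`a = λT²σT²`, `b = λR²σR²`, `c = λINT²σINT²` (or `λUM²σUM²`), `d = σOM²`,
`e = σε²`: `MIICC = (a+d)/τ`, `RMS = b/τ`, `IMS = c/τ`, `UMS = (b+c)/τ`,
`L2Con = a/(a+d)`, `L1Con = a/τ`, `L1OMS = d/τ`, `REL = τ/(τ+e)` with
`τ = a+b+c+d`. Two-level parameter sets satisfy the restrictions
`RMS = 0`, `IMS = UMS`. Identities (`MIICC + UMS = 1`,
`L2Con + L2OMS = 1`, reference `MIICC + RMS + IMS = 1`, component sums =
total variance) hold to numerical precision and are fuzz-tested.

Two reporting modes are first-class: **plug-in** (evaluate at a point
estimate; default for ML fits) and **per-draw** (evaluate per posterior
draw, report posterior means and central 95% credibility intervals;
default for Bayesian fits). The posterior mean of a ratio is not the ratio
of posterior means, which is why published per-draw summaries can differ
from plug-in values evaluated at posterior means by a few thousandths.
Report tables round half-even to 3 decimals; full precision is always
retained.

## Simulator

`simulate_ratings` is the exact generative mirror of the model equations
with construct-blocked missingness from the rater assignment; it supports
shared raters (with optional cross-construct rater/interaction
covariances), returns the latent draws for recovery diagnostics (the
estimators never see them), and is bitwise reproducible given a seed. Its
defaults in examples and tests are the study conditions: 202 targets, 4 + 3
disjoint raters, 3 indicators per construct, generating values from the
shipped published estimates. What it does **not** emulate: ordinal
response scales (unless the Likert option is switched on), rater drift
over time, nonignorable missingness, or target–rater assignment designs
other than crossed-with-blocking. Passing recovery tests therefore speak
to the estimators under the model, not to robustness against those
features of real data.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which the checked properties are stable:
recovery coverage uses 20 replications of the study design with 2 chains ×
4000 iterations; χ² calibration uses 50 ML fits at 200 targets; posterior
predictive calibration averages 3 model-true datasets (ppp of a single
dataset is itself a random variable) with 150 replications each;
Gibbs-kernel correctness uses a 100-target single-indicator sub-model
against 1-D quadrature. The full-length analyses of a real study (auto
mode to PSR < 1.1, or the fixed 10^6-iteration fallback) run in minutes to
tens of minutes.

## Known limitations

* Estimation requires each rater to score exactly one construct (shared
  raters are detected and must be dropped from one construct, mirroring
  common practice); cross-construct rater covariances are therefore
  flagged but never estimated.
* The ML engine requires balanced construct-blocked data.
* No ordinal/graded-response variants; no covariates for rater or
  interaction effects; no marginal-likelihood (Bayes factor) computation.
* DTCC rater-effect variances with 3–4 raters are weakly identified: wide
  posteriors, slow mixing (the study analysis itself needed a 10^6
  iteration fallback), and low posterior-predictive power at the rater
  level.
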