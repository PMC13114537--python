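# Methods

## Model

Lifetimes at stress level k (k = 1, …, m+1) follow the exponentiated
Rayleigh law

    F_k(t) = (1 − e^{−β_k t²})^α,
    f_k(t) = 2 α β_k t e^{−β_k t²} (1 − e^{−β_k t²})^{α−1},

with a shape α > 0 common to all levels and level-specific scales β_k > 0
(units 1/time²).  The shape alone controls the density and hazard shapes:
the density is decreasing for α ≤ 1/2 and unimodal above; the hazard is
increasing for α ≥ 1/2 and bathtub-shaped (divergent at both ends of the
support, interior minimum) below — a direct consequence of
f ∝ t^{2α−1} near the origin.

Stress rises at fixed times τ₁ < … < τ_m.  Under the cumulative exposure
model a unit's survival depends only on the exposure accumulated so far, so
the composed CDF on level k is F_k(c_{k−1} + t − τ_{k−1}) where the offset
c_{k−1} solves the continuity condition

    F_k(c_{k−1}) = F_{k−1}(c_{k−2} + τ_{k−1} − τ_{k−2}),   c₀ = 0.

Because the ER CDF argument is β t², this recursion gives

    c_{k−1} = Σ_{j<k} sqrt(β_j / β_k) (τ_j − τ_{j−1}),

i.e. **square-root** scale ratios.  (The linear-ratio offsets familiar from
exponential-type step-stress models belong to families whose CDF argument
is β t; applied here they would leave the composed CDF discontinuous at
every change time.)  The composed CDF is continuous by construction; the
density has jump discontinuities at the τ_k, where this implementation
returns the right-limit branch.  CDF level membership uses the half-open
convention (τ_{k−1}, τ_k].

Higher stress shortens expected life.  The ER mean is proportional to
1/sqrt(β) at fixed α (computed here by adaptive quadrature of the survival
function — only monotonicity in β is ever used), so the physical ordering
is exactly β₁ ≤ β₂ ≤ … ≤ β_{m+1}.

## Order-restricted maximum likelihood

The restriction is handled by the ratio reparameterization
λ_k = β_k / β_{k+1}, which turns the ordering into box constraints
0 < λ_k ≤ 1 on (α, λ₁..λ_m, β_{m+1}); λ_k = 1 encodes the boundary
β_k = β_{k+1}.  The fitting loop:

1. maximize the log-likelihood over all coordinates with **no upper bound**
   on the λ_k (log-scale coordinates impose positivity; L-BFGS-B,
   ftol 1e-12, gtol 1e-8);
2. if every λ_k ≤ 1 (+1e-8 tolerance), accept;
3. otherwise freeze **all** violators at exactly 1 simultaneously,
   re-maximize the remaining free coordinates, and re-check; at most 100
   outer iterations (two or three suffice in practice).

Initialization: α₀ = 1, λ_{k,0} = 0.5, β_{m+1,0} from the last-level
squared effective exposures (pooled 1/mean(t²) when that level is empty),
plus four jittered restarts with fixed seeds.  Multi-start matters: for
small samples with near-tied scales the likelihood develops a long flat
ridge in α (the bundled fish data is the canonical case — two ratios bind
and the profile in α is nearly flat over an order of magnitude), and a
single start can stall far from the optimum.

Standard errors come from the observed Fisher information, the negative
Hessian of the log-likelihood in the ratio coordinates at the optimum,
computed by central second differences with per-coordinate relative steps
(1e-3) and one Richardson extrapolation step (h and h/2 combined as
(4D(h/2) − D(h))/3).  If any eigenvalue falls below 1e-10 — common when
ratios sit on the boundary — a ridge 1e-6·I is added before inversion.
Wald intervals on (α, λ, β_{m+1}) use the diagonal; intervals for the
original scales β_k = (Π_{j≥k} λ_j) β_{m+1} use the delta method,
∂β_k/∂λ_j = β_k/λ_j for j ≥ k and ∂β_k/∂β_{m+1} = Π_{j≥k} λ_j.  Every
lower limit is truncated at zero (all parameters are positive; near-boundary
Wald intervals routinely cross zero at small n).

## Bayesian inference

Priors: α ~ Gamma(a₀, b₀), β_{m+1} ~ Gamma(a_{m+1}, b_{m+1}) (shape/rate),
λ_k ~ Beta(a_k, b_k) — supported exactly on the constrained space, so the
order restriction holds a priori.  Defaults are near-noninformative:
a₀ = b₀ = a_{m+1} = b_{m+1} = 1e-4, Beta(1, 1) on each ratio, N = 10,000
draws.

The posterior factorizes into a directly samplable hierarchy — λ_k
marginally uniform under the proposal, β_{m+1} | λ ~ Gamma(n + a_{m+1},
h₁(λ)) with h₁ the prior rate plus ratio-weighted squared effective
exposures, and α | λ, β_{m+1} ~ Gamma(n + a₀, h₂) with h₂ the prior rate
minus Σ ln(1 − e^{−β_k s²}) — leaving a residual importance weight h
(beta-prior factors, the effective-time product, the reciprocal
(1 − e^{−·}) factors, and the two gamma normalizers).  All weights are
accumulated in log space and normalized by log-sum-exp: h multiplies ~n
factors and overflows double precision already around n ≈ 50.  One seed
determines the full draw stream in a fixed order (λ block, then β, then α).
The effective sample size 1/Σw² is always reported and a warning fires
below 50.  Monte-Carlo standard errors of weighted means use the
delta-method ratio-estimator formula sqrt(Σ w_i²(g_i − ĝ)²).

Credible intervals operate on the weight-sorted sample with cumulative
weights C_k.  The symmetric interval takes the values at the smallest
indices reaching γ/2 and 1 − γ/2.  The HPD interval scans all start
indices and keeps the narrowest interval whose mass meets the coverage; the
end index is the first one whose cumulative mass reaches 1 − γ (so realized
mass is ≥ the nominal level — the discrete tie-break is one order statistic
and immaterial at N = 10⁴), implemented as an O(N) two-pointer sweep that
the tests verify against the literal quadratic scan.

With one level and the shape fixed at 1 the model collapses to a Rayleigh
likelihood with a conjugate Gamma(n + a, b + Σt²) scale posterior; the
sampler exposes a fixed-shape mode precisely so this closed form can serve
as an oracle.

Caveat: with several levels and small n the uniform proposal for λ is far
from the posterior and the weights are heavy-tailed; on the bundled fish
data the ESS is typically 30–150 out of 10,000, so posterior summaries
carry visible seed-to-seed variability.  ESS should always be inspected.

## Goodness of fit and model comparison

With F the fitted composed CDF and t_{i:n} the order statistics,

    D  = max_i max(|i/n − F(t_{i:n})|, |F(t_{i:n}) − (i−1)/n|),
    W² = 1/(12n) + Σ_i (F(t_{i:n}) − (2i−1)/(2n))².

p-values treat the fitted parameters as known: the KS p-value uses the
exact finite-n null distribution (the limiting law is visibly wrong at
n = 15), the CvM p-value the asymptotic one.  No estimation-adjusted
(Lilliefors-type) calibration is attempted.  Information criteria:
AIC = −2ℓ + 2p, BIC = −2ℓ + p ln n, HQIC = −2ℓ + 2p ln ln n,
CAIC = −2ℓ + p(ln n + 1), with p = m + 2 free parameters minus the number
of ratios bound at 1 in the fit.

## Synthetic data

The generator inverts the composed CDF directly: draw u ~ U(0,1), locate
the level by comparing u with p_k = F(τ_k), and solve the matching ER
branch, t = τ_{k−1} + sqrt(−ln(1 − u^{1/α})/β_k) − c_{k−1}.  Draws of
exactly 0 or 1 (probability zero) are redrawn to avoid degenerate or
infinite times.  It emulates complete (uncensored) samples under fixed,
known change times with correctly specified ER margins and exact CEM
linkage; it does not emulate censoring, covariate-dependent stress,
level-varying shapes, or model misspecification — so passing simulation
checks demonstrate correctness of the inference machinery under the model,
not robustness of the model itself on field data.

## Simulation harness

Replicate r of a study uses the independent seed stream
SeedSequence(entropy=base_seed, spawn_key=(r,)): studies are reproducible
bit-for-bit and parallelizable.  Replicates whose fit fails are excluded
and counted (not redrawn).  Reported metrics per parameter: average
estimate, MSE, average interval length, coverage in percent (an interval
truncated at zero covers if the truth lies in [max(0, lo), hi]), and the
percentage of replicates with each adjacent scale pair tied (taken from the
boundary flags of the final fit).  QQ diagnostics standardize the replicate
estimates by their empirical mean and SD — the check is the shape of the
sampling distribution, nothing more.

Default check sizes keep runs desk-scale: the frequentist reference-cell
study uses 500 replications and the Bayesian one 200 (at N = 10,000 draws
per replicate); comparisons against external summary values use 2–3
Monte-Carlo standard errors computed from the replicate spread, or ±3
percentage points for coverages.

## Numerical choices

- ln(1 − e^{−x}) via log(−expm1(−x)) below ln 2 and log1p(−exp(−x)) above;
  (1 − e^{−x})^α as exp(α · that).
- Density at t = 0: limit value (0 for α > 1/2, sqrt(β) at α = 1/2, +inf
  below).
- Nonpositive parameters in the likelihood return −inf with a warning so
  optimizers can wander safely on the log scale.
- Binding tolerance 1e-8 on λ; bound ratios frozen at exactly 1.
- Times are stored at full input precision; a failure time exactly equal to
  a change time is rejected at load (ambiguous level membership).

## Known limitations

- The shape can be weakly identified in small samples: the profile
  likelihood in α flattens and point estimates of α become unstable even
  when the fitted CDF (and hence the GoF statistics) is stable.  The fish
  data shows this: wide α intervals and a flat ridge, while KS/CvM barely
  move along it.
- Wald intervals near the boundary rely on a ridge-regularized information
  matrix and zero truncation; their coverage for scales close to equality
  is approximate.
- Importance sampling degenerates as m grows or n shrinks (see ESS caveat
  above); MCMC would be the natural escalation and is out of scope.
- Complete samples only: no censoring, no covariates, no competing link
  models (tampered failure rate / tampered random variable).
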