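# Methods

## Model and estimands

The data-generating and analysis model is a single-mediator linear-Gaussian
system for a two-arm randomized trial:

    M_i ~ Normal(i_m + a·X_i,                    σ_m)
    Y_i ~ Normal(i_y + c′·X_i + d·Z_i + b·M_i,   σ_y)

X_i ∈ {0, 1} is the randomized treatment, Z_i a continuous covariate
(stress severity), M_i the mediator (adverse-event severity) and Y_i the
outcome (fatigue severity). All three continuous variables are treated as
unbounded severity scores on a nominal 0–10 scale; they are deliberately
never clipped or discretized, so the Gaussian likelihoods are exactly
correct for the simulated data and estimator properties measured against
them are interpretable. The estimands are the eight parameters plus the
direct (c′), indirect (a·b) and total (c′ + a·b) effects, computed per
posterior draw so that total = direct + indirect holds exactly in every
retained sample.

Assumptions inherited from this structure: randomization makes X exogenous;
there is no exposure–mediator interaction, a single mediator, and no
unmeasured mediator–outcome confounding beyond Z. These are the standard
identification conditions under which the product-of-coefficients
decomposition is causal.

## Priors and sampler

All six coefficients (including intercepts) receive independent
Normal(0, 10²) priors; both residual variances receive
InverseGamma(0.001, 0.001). On severity scales of magnitude ~10 these are
weakly informative: the prior standard deviation exceeds any plausible
effect by an order of magnitude, and posterior means at n = 75 move by well
under 10% when the coefficient prior SD is widened to 100 (tested).

Conjugacy makes the model a pure Gibbs problem, sampled from scratch:

* coefficient block per equation: β | σ², data ~ MVN(Q⁻¹r, Q⁻¹) with
  Q = X'X/σ² + I/τ² and r = X'y/σ², drawn via Cholesky factorization;
* variance per equation: σ² | β, data ~ InvGamma(a₀ + n/2, b₀ + SSR/2).

The two equations share no parameters, so their updates are exact and
independent given the data — an exactness property of the factorized
likelihood, not an approximation. With a residual variance held fixed (a
validation mode), the coefficient draws are iid from the exact conjugate
posterior; tests exploit this to compare the sampler against the closed
form at 3 Monte-Carlo standard errors, and against a brute-force grid
maximizer of the log posterior density.

Defaults: 4 chains × 2000 retained draws after 1000 burn-in. Chains start
from OLS estimates jittered by Normal(0, (0.5·SE)²) and residual variances
at OLS × Uniform(0.5, 2), so the split-chain R-hat (rank-normalized, via
arviz, alongside bulk ESS) is informative; a fit is flagged converged only
if every quantity's R-hat < 1.01. Constant (degenerate) draw arrays return
R-hat = 1 by convention. Intervals are equal-tailed posterior quantiles —
order-statistic exact, unlike HPD. σ² is sampled on the variance scale and
reported as σ = √σ².

## Synthetic dialogues

The dialogue generator stands in for LLM role-play with a deterministic
template bank: per router node at least three surface variants, selected by
a CRC32 hash of (seed, subject id, node id). The router asks a greeting, a
yes/no fatigue probe ("Yes" iff Y ≥ 3.0 by default — the branch rule is a
design choice, since a yes/no answer has no canonical numeric link), a
branch-specific stress question, and a side-effect question; both branches
also elicit numeric severities for fatigue, stress and side effects, which
embed Y, Z, M rounded to `render_precision` decimals (default 2). Rounding
in the rendered text is the pipeline's only information loss; at precision
4 the transcript path and the direct ground-truth path give simulation
metrics agreeing to 10⁻² per cell (tested).

What this emulates: the *statistical* content of chatbot-collected PROs —
branching elicitation, complete per-subject triples, values recoverable
from text. What it does not: linguistic variability, ambiguous or
inconsistent self-reports, missing answers, free-text extraction error.
Passing tests therefore certify the estimator and pipeline under faithful
extraction, not robustness of natural-language understanding.

Seed discipline: arm allocation uses SeedSequence(seed, spawn_key=(0,));
subject i uses spawn_key=(1, i), so enlarging a cohort leaves earlier
subjects' noise draws untouched (the 1:1 permutation itself necessarily
changes with n). Replication r of a study uses master_seed + r, with cohort
and MCMC seeds split from it by SeedSequence.generate_state — studies are
extensible without recomputing earlier replications, and both pipeline
paths of a replication share identical randomness.

## Simulation study and metrics

Default study conditions: 100 replications of 75 subjects randomized 1:1,
truth a=0.4, b=0.5, c′=0.3, d=0.2, i_m=1.0, i_y=2.0, σ_m=σ_y=0.5, and
Z ~ Normal(5, 2²). The effect sizes are moderate-and-detectable at n = 75
(standardized paths ≈ 0.3–0.8 of a residual SD); Z's location and scale put
severities on the nominal 0–10 scale. All truths are config-driven, so
other regimes (including the a = 0 null, used for calibration testing) are
one config away.

Per estimand g with per-replication posterior mean ĝ_r and interval
[l_r, u_r]:

    Bias = mean(ĝ_r − g)            RMSE = √mean((ĝ_r − g)²)
    Coverage = mean(1{l_r ≤ g ≤ u_r})    Interval_Width = mean(u_r − l_r)

computed over converged replications only; non-converged replications are
flagged, excluded and counted, never silently included, and a study with
fewer than two usable replications fails loudly. RMSE² = Bias² + Var(ĝ)
holds by construction and is asserted to 10⁻¹⁰.

## Numerical and design notes

* Degenerate inputs: a single-arm table raises a degenerate-design error;
  a constant covariate (or any collinear design column) a rank-deficiency
  error; fewer than 5 subjects a config error. Severity answers must
  contain exactly one numeric token — zero or several raise distinct
  parse errors naming the subject and node.
* The generator accepts σ = 0 for noiseless checks; note that with σ_m = 0
  the mediator is an exact linear function of (1, X) and b becomes
  unidentified in the outcome equation, so noiseless-limit validation keeps
  σ_m a few orders of magnitude above σ_y instead.
* Problem sizes used by the test suite were chosen to give tight Monte-Carlo
  error at interactive runtimes: the headline study at its full 100 × 75
  scale, oracle comparisons at n = 40 over 20 datasets, round-trip property
  checks over 1000 mini-cohorts, consistency checks up to n = 5000 (MCMC)
  and n = 50,000 (OLS recovery of the generating process).

## Known limitations

* Estimator quality figures certify the well-specified case: the analysis
  model and the generator share the same likelihood. Misspecification
  (non-Gaussian severities, exposure–mediator interaction, multiple
  mediators, missing dialogue turns) is out of scope.
* The InverseGamma(0.001, 0.001) variance prior, while conventional, is not
  uninformative for σ near 0; at n = 75 its effect is negligible (σ rows
  show near-nominal coverage in the default study).
* Transcripts exercise a fixed template grammar; the extractor is exact by
  construction on that grammar and makes no claim about free-form text.
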