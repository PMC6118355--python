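# Methods notes

## Task model

The package models discriminant threat conditioning at the trial level only:
an ordered sequence of CS+ / CS- presentations with binary US outcomes.
Defaults follow the standard session: 80 trials per CS in two blocks, 50% of
CS+ trials reinforced, the first trial of each block a reinforced CS+, and
the remaining trials of each block uniformly permuted. Blocks are balanced —
each holds an equal share of each CS and of the reinforced CS+ trials; the
first-trial rule and two blocks are the only hard constraints, balance is a
symmetry choice. Stimulus timing, modality and inter-trial intervals do not
enter trial-level model fitting, so delay and trace variants share one
generator distinguished by a metadata tag.

## Learning models and conventions

All models output the state held *before* a trial's outcome (the prior), so
the first presentation of either CS carries the initial value; learning
states are per-CS and updated only on that CS's trials. Specific choices the
equations leave open:

- **Hybrid initial associability.** The hybrid model has a single fitted
  parameter (k); its initial associability is a fixed constant, set to 0.5
  to match the x₀ = 0.5 convention, and exposed as `eta0` in the fitting and
  simulation configs.
- **Per-CS associability.** The hybrid associability is maintained per CS
  (updated only on that CS's trials) with k shared across CS, consistent
  with the per-CS value update.
- **Pooled count for UN.** The habituation-only model is blind to CS
  identity, read as one observation count over all trials. Counting per CS
  instead changes its z only by an additive constant absorbed by β₀; the
  `prior_counts` flag likewise switches between before-trial and after-trial
  counts, which differ by a near-constant shift. Before-trial counts are the
  default for consistency with the uncertainty term v_t of the beta-binomial
  observer.
- **Parameter ranges.** η and k live in the open unit interval; the fitting
  grid covers [0.005, 0.995]. At η = 1 the RW update degenerates to copying
  the last outcome, so the boundary is excluded by contract.

A useful identity (asserted in the tests): the beta-binomial prior mean
follows a delta rule with effective learning rate 1/(α+β+1), i.e. an RW
learner whose rate decays hyperbolically with the number of observations of
that CS. This is the formal sense in which the ideal observer differs from
fixed-rate RL: early trials move predictions a lot, late trials barely.

## Fitting

The observation function is linear, `y = β₁z + β₀ + ε` with i.i.d. Gaussian
noise; the objective is the residual sum of squares over unreinforced trials
only (all trials feed the learner; reinforced trials are masked from the
objective to avoid US-evoked contamination). For any fixed learning
parameter the optimal (β₀, β₁) are the OLS solution, so they are profiled
out analytically and only η or k is searched: a 101-point grid over
(0.005, 0.995), then bounded scalar minimisation (objective tolerance 1e-8)
started from the three best grid-local minima. The search is deterministic
and seed-free; β₁'s sign is unconstrained (habituation-like variables such
as v_t need negative slopes with rising magnitude).

BIC = p·ln T + T·ln(RSS/T) with p counting learning parameters plus the two
regression weights (p = 2 for BM/BC/UN/NL, 3 for RW/HM1/HM2) and T the
number of unreinforced trials. On (near-)noiseless data RSS is clamped at
1e-12·TSS (flagged with a warning) to keep BIC finite. Explained variance is
1 − RSS/TSS on the same trials and may be negative for poor models.

## Group-level selection

Random-effects BMS follows the variational Dirichlet scheme: iterate
participant responsibilities (softmax of log evidence plus digamma terms)
against Dirichlet counts until the concentrations move less than 1e-8
(cap 10⁴ iterations). Log evidence is −BIC/2 by default (only differences
within a participant matter). Exceedance probabilities use the closed Beta
form for two models and otherwise 10⁶ Monte-Carlo Dirichlet draws with a
fixed seed. The Bayes omnibus risk compares the variational free energy of
the RFX model against the equal-frequency null, BOR = 1/(1+exp(F₁−F₀)), and
protection is the convex mixture pxp = (1−BOR)·xp + BOR/K. Family inference
aggregates member evidences per participant by log-sum-exp minus ln(family
size) — a uniform within-family prior, so a large family gains nothing from
membership alone — and runs the same scheme over families; a singleton
partition reduces exactly to model-level selection.

## Synthetic data

The generator emulates the statistical structure of single-trial amplitude
estimates, not the physiology: per participant it draws a fresh randomized
design, learning parameters η, k ~ U(0.05, 0.95), slope β₁ lognormal with
median 1 (log-sd 0.5), intercept β₀ ~ N(1, 0.3), and then calibrates the
noise so the true model's population R² on unreinforced trials equals a
target (default 0.2, the explained-variance regime typical of real SCR/PSR
estimates): σ² = β₁²·Var(z)·(1−R*)/R*. Noise is homoscedastic within a
participant and heterogeneous across participants through the calibration.
All randomness flows from one root SeedSequence via per-participant spawned
streams, so any subset is bit-reproducible.

What the generator does **not** emulate: serial correlation of autonomic
noise, amplitude floors/skew, habituation mechanisms outside the model
space, upstream estimation error of the amplitudes themselves, or
participants whose responses carry no signal. Passing recovery tests
therefore show what the *design and selection machinery* can do when every
participant carries calibrated signal — not what survives real-data noise
structure.

## Model recovery

For each true model, 64 experiments of 20 participants are simulated
(full-size runs use 256; 64 keeps a desk-scale run in minutes on one CPU),
all seven models are fitted to every participant, and the group winner is
the argmax of the protected exceedance probability over −BIC/2 evidences
(a summed-BIC fixed-effects criterion is available behind
`criterion="ffx"` for sensitivity analysis). Winners are tallied into
model- and family-level confusion matrices. Within the recovery loop the
Monte-Carlo draw count is reduced to 2×10⁵: the winner is an argmax, which
is insensitive to MC noise away from exact ties. Each (true model,
experiment) cell derives its own seed from the root by spawn key, so the
grid is order-independent.

Under these conditions recovery is close to ceiling: with every simulated
participant calibrated to 20% explained variance and a median slope of 1,
twenty participants' pooled evidence separates even the similar candidates
(the residual confusions are RW/hybrid/BM, whose prediction-type traces can
mimic one another). Recovery rates reported for comparable designs in the
literature are lower; those studies drew simulation parameters from fits to
real participants, where slopes near zero and poorly identified learning
rates leave many simulated participants near-uninformative. Recovery rates
are thus a property of the assumed parameter population as much as of the
design; the generator's distributions are documented above precisely so
that this dependence is explicit.

## Manipulation check

The CS × Trial contrast fits `amplitude ~ 1 + CS*Trial` with a random
intercept per participant (REML, via statsmodels MixedLM) on unreinforced
trials. Trial is a continuous session-wide index by default (`per_cs` coding
available). F statistics for the three 1-df fixed effects are squared Wald
statistics with denominator df by the within-group residual rule
N − n_participants − 3; p-values are Bonferroni-corrected across datasets
(default factor 4). Zero-variance input short-circuits to F = 0 rather than
attempting a degenerate mixed-model fit.

## Known limitations

- BIC is the only evidence approximation; no free-energy or cross-validated
  alternatives.
- The Gaussian-noise linear observation function is assumed, not tested;
  heteroscedastic or multiplicative noise would bias RSS-based comparison.
- Recovery conclusions are conditional on the generator's parameter
  population (see above).
- Exact numerical agreement with fits produced by other optimisers is only
  guaranteed up to optimiser equivalence; the grid+refinement contract here
  is deterministic and reproducible but not unique.
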