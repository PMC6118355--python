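# threatlearn

Trial-by-trial computational modelling of Pavlovian threat conditioning.

In discriminant threat conditioning, one cue (CS+) is followed by an aversive
outcome (US) on half of its presentations while a second cue (CS-) is never
reinforced. Autonomic responses — skin conductance (SCR) and pupil size
(PSR) — track the learner's threat prediction trial by trial. `threatlearn`
is for researchers who have single-trial anticipatory amplitude estimates
(e.g. from psychophysiological modelling) and want to ask *which learning
algorithm, read out through which observation function, best explains them*.

## Model space

Every model produces a per-trial observation variable `z_t` (the state held
*before* the trial's outcome) that maps linearly onto measured amplitudes:

    y_t = β₁·z_t + β₀ + ε_t,   ε_t ~ N(0, σ²)

| model | z_t | learning params | family |
|-------|-----|-----------------|--------|
| RW    | associative strength x_t, `x_t = x_{t-1} + η(u_{t-1} - x_{t-1})` | η | O |
| HM1   | associability η_t of the hybrid RW/Pearce-Hall model | k | S |
| HM2   | associative strength x_t of the hybrid model | k | O |
| BM    | Beta prior mean E[θ] = α/(α+β) of a sequential beta-binomial observer | — | O |
| BC    | prior uncertainty + prior mean, v_t + E[θ], v_t = −ln(α+β) | — | C |
| UN    | pooled observation count, −ln(α+β), blind to CS identity | — | N |
| NL    | constant CS difference {1, 0} | — | N |

Hybrid updates: `η_t = k·|x_{t-1} − u_{t-1}| + (1−k)·η_{t-1}`,
`x_t = x_{t-1} + η_{t-1}·(u_{t-1} − x_{t-1})`. The beta-binomial observer
starts from the uninformative Beta(1, 1) prior per CS.

Fitting minimises the residual sum of squares over unreinforced trials only
(US-evoked responses would contaminate the objective); `β₀, β₁` are profiled
out by closed-form OLS and any learning parameter is searched on a dense
grid with bounded local refinement. Model evidence is approximated by
`BIC = p·ln T + T·ln(RSS/T)`, and group-level comparison uses random-effects
Bayesian model selection: a variational Dirichlet posterior over model
frequencies, exceedance probabilities, the Bayes omnibus risk (BOR), and
protected exceedance probabilities `pxp = (1 − BOR)·xp + BOR/K`, at the
level of single models or of model families.

A synthetic-data generator (`simulate`) and a recovery study (`recovery`)
quantify the design's a-priori ability to discriminate the models, and
`contrast` provides the CS × Trial linear mixed-effects manipulation check.

## Worked example

Simulate one 20-participant experiment from the combined observer (BC) at
the empirically typical 20% explained variance, fit all seven models to each
participant, and compare them at the group level:

```python
import numpy as np
from threatlearn import (
    GeneratorConfig, simulate_experiment, fit_all_models, evidence_from_bic,
    rfx_bms, family_bms, winner, MODELS,
)

data = simulate_experiment(GeneratorConfig(true_model="BC", n_participants=20, seed=7))
bic = np.array([
    [fit_all_models(y, seq)[m].bic for m in MODELS]
    for seq, y in zip(data.sequences, data.amplitudes)
])
log_ev = evidence_from_bic(bic)        # log p(y|m) ≈ -BIC/2

res = rfx_bms(log_ev, labels=list(MODELS))
for m, pxp in zip(res.labels, res.pxp):
    print(f"{m:4s} pxp = {pxp:.3f}")
print("winner:", winner(res)[0], " BOR =", round(res.bor, 4))

fam = family_bms(log_ev, list(MODELS))
print({f: round(p, 3) for f, p in zip(fam.labels, fam.pxp)})
```

Output:

```
RW   pxp = 0.000
HM1  pxp = 0.000
HM2  pxp = 0.000
BM   pxp = 0.000
BC   pxp = 1.000
UN   pxp = 0.000
NL   pxp = 0.000
winner: BC  BOR = 0.0
{'C': 1.0, 'N': 0.0, 'O': 0.0, 'S': 0.0}
```

The generating model is identified with protected exceedance probability
1.00 (BOR ≈ 0: the data decisively reject equal model frequencies), and the
family comparison attributes the signal to the combination family C —
expected outcome plus its decaying uncertainty.

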