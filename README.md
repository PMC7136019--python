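# socstruct

Social structure learning on a simulated ally-learning task: who counts as
"us", and how would a learner figure that out from sparse behavioral
evidence alone?

`socstruct` implements, end to end and on fully synthetic data, the
model-based analysis pipeline for a task in which a participant states their
own stance on eight binary political issues per run while predicting — and
receiving feedback on — the stances of three novel agents (A, B, C), then
chooses to ally with A or B on an unknown issue. The inter-agent structure
is fixed: A's choices are the elementwise inverse of B's, B and C agree on
5/8 issues, A and C on 3/8. The package is aimed at computational cognitive
neuroscientists who want a tested reference implementation of the competing
trial-by-trial allyship models, the parametric-modulator GLM machinery, and
the group-level Bayesian model selection that adjudicates between them.

## The three models

For each guess event (8 trials x 3 agents per run) the package computes a
parametric modulator under three accounts of how allyship is estimated:

- **Dyadic similarity** — a Laplace-smoothed agreement rate between the
  participant and each agent:

      S_d(t) = (k + 1) / (t + 1),

  with `t` the 1-based trial and `k` the agreements on trials `1..t-1`, so
  every agent starts at 0.50.

- **Feature similarity-over-agents** — a second-order similarity: the
  Pearson correlation between the participant's and the agent's rows of the
  4x4 matrix of all pairwise `S_d` values over {P, A, B, C}, rescaled by
  `(r + 1)/2` and mapped through log-odds.

- **Latent structure learning** — exact Bayesian inference over the 15
  partitions z of {P, A, B, C}, with a Chinese restaurant process prior

      P(z | alpha) = alpha^K Gamma(alpha) prod_k Gamma(T_k) / Gamma(M + alpha),
      alpha = 2,

  and a Dirichlet-multinomial marginal likelihood over the observed binary
  choices (concentration gamma = 1). The modulator is the posterior
  co-membership probability P(z_agent = z_P | choices observed so far); it
  is the only model that updates within a trial, using earlier agents'
  feedback on the current issue.

Downstream, the package fits ally-choice logistic regressions with
likelihood-ratio tests, builds HRF-convolved first-level design matrices
over simulated 12-minute runs (TR = 1.5 s), recovers GLM amplitudes from
synthetic BOLD, decodes regressor-specific signal via the ridge-regularized
inversion `(Y - sum_{i != t} b_i X_i) b_t / (b_t^2 + lambda)` with
`lambda = 1`, and performs random-effects Bayesian model selection
(expected frequencies, exceedance probabilities, Bayesian omnibus risk, and
protected exceedance probabilities `PXP = EP (1 - BOR) + BOR / K`) over
BIC-based log model evidences assembled by a leave-one-subject-out harness.

## Worked example

```python
from socstruct import latent, task

for condition in ("high_C", "low_C"):
    run = task.generate_behavioral_design(condition, seed=3).schedule
    p_b = latent.endpoint_comembership(run, "B", alpha=2.0)
    print(condition, round(p_b, 3), run.participant_agreement("B"))
```

prints

```
high_C 0.275 4
low_C 0.158 4
```

Agent B agrees with the participant on exactly 4/8 issues in *both*
conditions, yet the posterior probability that B belongs to the
participant's group is 0.275 when C (who agrees with B on 5/8) sides with
the participant on 7/8 issues, and only 0.158 when C sides with them on
1/8. A dyadic account assigns B the same value (5/10) in both conditions —
this condition sensitivity is the latent model's signature prediction, and
`examples/02_latent_structure.py` walks through the full posterior. The
other example scripts cover the similarity models, the choice regressions,
neural decoding, and group model selection; each prints the numbers it
computes and a short note on what they mean.

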