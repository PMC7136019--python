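# Methods

This note records the models implemented in `socstruct`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Task structure and the synthetic generator

A session is six runs. Each run has 8 binary issues; the participant states
a stance and then guesses, with feedback, the stances of agents A, B, C in
a random within-trial order. The inter-agent agreement structure is fixed
by design — A is B's elementwise inverse (0/8 agreement), B–C agree on 5/8,
hence A–C on 3/8 — and the generator enforces it exactly: B's column is
drawn uniformly (optionally constrained to a requested participant
agreement count), A is set to ¬B, and C is drawn uniformly from the
explicitly enumerated set of the 2^8 columns satisfying the B–C constraint
and any requested participant-agreement count. Sampling from the enumerated
feasible set makes "uniform over schedules satisfying the constraints" true
by construction, and infeasible pattern requests fail with the violated
constraint named.

Participant stances are i.i.d. Bernoulli(0.5) by default: the task's issues
were selected to be maximally contentious (near 50/50 splits in survey
data), so an unbiased coin is the natural surrogate; `stance_p` is
configurable. Under this default the participant–agent agreement counts are
Binomial(8, ½), concentrated on 3–5; the two behavioral-design fixtures pin
them instead at B = 4/8 with C = 7/8 ("high-C") or 1/8 ("low-C").

What the generator does **not** emulate: real stance correlations across
issues (ideological coherence), missed responses, response times, any
deliberate experimenter variation of agreement counts across runs, and the
face stimuli. Consequences for interpretation are discussed under
*Limitations*.

Guess responses (the participant's predictions of each agent's choice) are
generated for completeness of the event tables but feed no model: none of
the three models consumes them.

## Allyship models

**Dyadic similarity.** `S_d(t) = (k+1)/(t+1)` with `t` the 1-based current
trial and `k` the participant–agent agreements over trials `1..t−1`. This
indexing is fixed by the model's worked values (0.50 at t=1; 2/3 and 1/3 at
t=2; 3/4 at t=3 after two agreements) and equals a Laplace-smoothed
agreement rate. Values reset to 0.50 at every run start (new agents). All
three agents at trial t share the same t; the model never uses within-trial
feedback.

**Feature similarity-over-agents.** A 4×4 symmetric matrix holds `S_d` for
all six pairs over {P, A, B, C} computed from completed issues, with an
exact unit diagonal. The feature value for an agent is the Pearson
correlation `r` between the participant's and the agent's full rows (all
four columns, diagonal included — excluding the pair's own columns leaves
2-vectors whose correlation is degenerately ±1), rescaled by the fixed
affine map `(r+1)/2` and mapped through log-odds. A data-dependent min–max
rescale was rejected because it would make a trial's modulator depend on
future trials. The rescaled value is clipped to `[ε, 1−ε]` with `ε = 1e−3`
before the log-odds so the value stays finite at `r = ±1`; on simulated
cohorts the clip never engages (|r| never reaches 1 in practice), so its
exact value is immaterial there.

**Latent structure learning.** The partition z of {P, A, B, C} has a CRP
prior `P(z|α) = α^K Γ(α) Π_k Γ(T_k) / Γ(M+α)` with α = 2, and the observed
binary choices have the Dirichlet-multinomial marginal likelihood with
concentration γ per option (2 options per issue). γ is not pinned down by
the source analysis; γ = 1 (uniform Dirichlet) is the least-informative
standard choice and is exposed in the config. With M = 4 there are B(4)=15
partitions, so the posterior is computed by exact enumeration — enumeration
is both the implementation and its own oracle; there is no sampling
anywhere in the inference. All arithmetic is in log space with `gammaln`,
normalized by log-sum-exp; tests verify agreement with a plain-arithmetic
brute-force recomputation to 1e−10.

The modulator for a guess event is the posterior probability that the
guessed-about agent shares the participant's group, computed by summing
posterior mass over partitions with `z_agent = z_P`. A product-of-marginals
variant (`method="marginal_product"`) is provided for comparison; a small
result worth recording is that under restricted-growth labelling with the
participant listed first the two coincide exactly for every
participant–agent query (the participant's label is identically 0), so the
distinction only matters for agent–agent queries, which the model never
makes.

The observation set at the guess for the agent in within-trial position o
of trial t contains: the participant's stances through issue t (the
participant responds before guessing), all agents' feedback through issue
t−1, and the current-issue feedback of agents guessed earlier in the trial.
The guessed-about agent's own current-issue choice is never included. The
value used is therefore the pre-feedback ("prior") estimate for that agent.
Prior co-membership is 1/(1+α) for every pair, so the series starts at 1/3
under α = 2; it resets at each run start.

## Choice behavior

Ally choices are simulated per run as
`chose_B ~ Bernoulli(logistic(c0 + b_B·x_B + b_C·x_C + b_BxC·x_B·x_C))`
where x are participant–agent agreement **counts** (0–8) by default;
proportion coding is available since the regression's predictor scale is
a genuinely open choice. The default slopes are (2.325, 1.322, −0.307) and
the default intercept −9.676 centers the linear predictor at the modal
agreement pattern (4, 4) so that simulated choice probabilities span both
outcomes — an intercept near zero under count coding would saturate the
logistic and make the slopes unidentifiable in recovery studies.

Fitting is fixed-effects maximum-likelihood logistic regression
(statsmodels), with Wald z, Wald 95% CIs and the log-likelihood; random
slopes are deliberately absent (they overfit this design), and a
subject-intercept variant is out of scope. Perfect separation or a constant
outcome is flagged on the fit and warned about, with a binomial-GLM
fallback for the point estimates. Nested models are compared by the LRT
`χ² = 2(ll_full − ll_reduced)` with df equal to the parameter-count
difference; calibration under the interaction-free null is verified at
α = 0.05 over 1000 replicates.

End-of-learning model predictions use the full 8-issue history (t = 9 for
the similarity models). Feature values are mapped back to the (0,1) scale
before logs (the log of a log-odds can be undefined). The behavioral
log-difference convention is `log(value_A) − log(value_B)` with outcome
"chose B", values clipped at 1e−6. The neural-augmented choice model
regresses `chose_B` on the model log-difference, then adds the decoded
neural log-difference **orthogonalized** (residual of an intercept + slope
projection) against the model log-difference, and reports the LRT of the
augmented against the base fit — so only extra-model neural variance can
improve the fit.

## Neural simulation, design matrices, decoding

Runs are 12 minutes at TR = 1.5 s (480 frames). Modelled events are the
eight self-choice onsets, 24 guess onsets, the two agent-photo onsets, and
the ally choice; fixation jitter between modelled events is uniform on
[3, 16] s. The full screen-by-screen sequence of the real task does not fit
a 12-minute run when a jittered fixation is placed after *every* screen at
this jitter's mean, so the simulator places fixations after self-choice,
feedback, photo and ally-choice events (feedback shares the guess screen)
and resamples a run's jitter vector in the rare case the events would
overrun the run; typical runs end near 560 s of events.

Regressors are stick functions convolved with the peak-normalized canonical
double-gamma HRF (10× oversampling, then decimation to the TR grid). The
modulator column is the guess stick train scaled by the raw modulator
values — **not** mean-centered and **not** orthogonalized against the
unmodulated guess regressor — plus per-run intercepts and optional
polynomial drifts. Temporal/spatial derivative nuisance regressors are
meaningful only for real scanner data and are omitted from simulation.
Synthetic voxel data are `Y = Xβ + N(0, σ²)`; white noise by default since
the package's claims are about recovery and calibration, not scanner
realism.

Collinearity diagnostics are computed on the modulator **value** series
(pre-convolution), per participant across all 144 guess events, as pairwise
Pearson correlations and `VIF = 1/(1−r²)`, with cohort means over
participants; a post-convolution variant is a one-line change and not
exposed.

Decoding follows the ridge-regularized GLM inversion
`signal = (Y − Σ_{i≠t} β̂_i X_i) · β̂_t / (β̂_t² + λ)` with λ = 1. As written
this returns the target's time course at **unit** amplitude in the λ→0
noiseless limit (the β̂ in the numerator cancels one power of β̂²), and
shrinks it by `β̂²/(β̂²+1)` at λ = 1; the β̂-weighted sum of decoded
components reconstructs Y in an orthogonal noiseless design. Event
amplitudes are the voxel-mean decoded signal averaged over [onset+3 s,
onset+7 s] (the HRF peak window; the summary window is otherwise
unconstrained). Because decoded amplitudes can be negative, the A-vs-B
log-difference applies one global affine shift (−min + 1e−3) across both
agents' amplitudes per participant before logs, and only when some
amplitude is non-positive; a plain difference is a trivial alternative if
the shift is unacceptable for a given analysis.

## Model scoring and group-level selection

Each model is scored per subject by the BIC of the Gaussian GLM of the
ROI-mean time series, `BIC = n ln(RSS/n) + k ln n`, converted to log model
evidence as −BIC/2. Scoring the first-level GLM of the ROI-mean series is
the most direct reading of "model fit in a cluster"; RSS is floored at
machine epsilon with a warning for pathological perfect fits.

Group selection is the standard variational random-effects scheme: a
Dirichlet(α₀ = 1) prior over model frequencies, iterated variational
updates of per-subject assignment responsibilities and the Dirichlet
posterior, exceedance probabilities by seeded Monte-Carlo sampling of that
posterior (10⁶ draws by default, drawn in blocks), the Bayesian omnibus
risk from the free-energy comparison of the equal-frequency null against
the random-effects model (`BOR = 1/(1+exp(F₁−F₀))`), and
`PXP = EP·(1−BOR) + BOR/K`, an identity the implementation satisfies
exactly. Only within-subject evidence differences matter; the
implementation shifts each row by its maximum for numerical stability and
is invariant to per-subject constants. With identical evidences BOR is not
literally 1 but approaches it from below as the cohort grows (≈0.84 at
N=10, ≈0.9+ at N=40): the free-energy gap is the complexity cost of the
frequency posterior, which grows logarithmically in N.

The leave-one-subject-out harness simulates a cohort whose ROI-mean signal
is generated from one model's modulator column (amplitudes: self 1.0,
guess 1.0, modulator 2.0, photos 0.5/0.5; noise σ = 0.5 by default — a
moderate SNR at which the generating model is recoverable), scores the
held-out subject's three designs per fold, and pools the resulting
subjects × models evidence matrix through the group analysis. A
frequency-mapping generator assigns subjects' generating models in stated
population proportions; the equal-proportion case is exactly the
equal-frequency null that BOR is designed to flag. (A within-subject
superposition of the three modulator series does not produce that null:
the summed series is systematically closer to the dyadic/feature columns
than to the latent one, so one model always wins.) Two runs per subject
are used in the harness — they already identify the generating model — to
keep the default suite fast; the design logic is identical at six.

## Reproducibility and problem sizes

Every stochastic step takes a seed; the pipeline derives all stage seeds
from one master seed and rerunning a config reproduces every artifact byte
for byte. Default problem sizes: 42 participants for cohort statistics
(matching the scanned sample), 500 subjects for slope-recovery studies,
1000 replicates for LRT calibration, 8–12 subjects and 2 runs for the LOSO
harness, 200 replicates for GLM unbiasedness. These keep the full test
suite and the `reproduce-all` pipeline in the minutes range on one CPU
while leaving Monte-Carlo error well inside the tested tolerances.

## Limitations

- The cohort surrogate reproduces the *structure* of the modulator
  collinearity but sits at the top of the real cohort's range: simulated
  dyadic–feature correlations (~0.977 mean) exceed the real mean (0.9614)
  because the surrogate lacks real-data heterogeneity (coherent stance
  patterns, designed variation in agreement counts, missed trials). The
  VIF `1/(1−r²)` amplifies that small excess substantially — the simulated
  dyadic–feature VIF is roughly 23 against the real 13.8 — so VIF-level
  agreement should not be expected from this generator, while the
  dyadic–latent VIF (~5.0 vs 5.06) agrees closely.
- Passing recovery tests on white-noise BOLD says nothing about autocorrelated
  scanner noise, motion, or spatial statistics; whole-brain inference is
  out of scope.
- The real study's published statistics (choice-regression coefficients,
  LRT values, PXP/BOR in specific regions) live in archived scanner data
  and are not recomputable here; the package's claims are the structural
  and calibration properties above.
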