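"""Simulate one ally-learning run and compute the two similarity models.

Builds a single run (8 political issues, agents A/B/C with the fixed
agreement structure: A = inverse of B, B-C agree on 5/8, A-C on 3/8),
then prints the trial-by-trial dyadic similarity and feature
similarity-over-agents values for each guess event.
"""

from socstruct import similarity, task

run = task.generate_run_schedule(seed=1)
print("participant stance:", run.participant_stance)
print("agreements with participant:",
      {a: run.participant_agreement(a) for a in task.AGENTS})

dyadic = similarity.dyadic_series(run)
feature = similarity.feature_series(run)

print(f"\n{'trial':>5} {'agent':>5} {'dyadic':>8} {'feature(log-odds)':>18}")
for (t, agent), d, f in zip(dyadic.events, dyadic.values, feature.values):
    print(f"{t:>5} {agent:>5} {d:>8.3f} {f:>18.3f}")

# The dyadic value is the smoothed agreement rate (k+1)/(t+1): it starts at
# 0.50 for every agent and drifts toward that agent's empirical agreement
# with the participant. The feature value is the log-odds of a rescaled
# correlation between the participant's and the agent's rows of the 4x4
# dyadic-similarity matrix: it moves even when the agent's own history is
# flat, because the other agents' histories reshape the matrix.
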