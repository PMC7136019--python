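"""Exact Bayesian latent-structure learning over {P, A, B, C}.

The model treats social group structure as a partition z of the four
individuals. The prior over partitions is the Chinese restaurant process
(CRP) with dispersion alpha,

    P(z | alpha) = alpha^K Gamma(alpha) prod_k Gamma(T_k) / Gamma(M + alpha),

where K is the number of groups and T_k their sizes. The likelihood of the
observed binary stances marginalizes per-group choice probabilities under a
Dirichlet(gamma) prior, giving the Dirichlet-multinomial marginal

    P(C | z) = prod_n prod_k Gamma(|X| g) / Gamma(T_kn + |X| g)
                              prod_c Gamma(L_knc + g) / Gamma(g),

with |X| the number of response options (2 here), T_kn the number of
individuals in group k observed on issue n, and L_knc how many of them chose
option c. Partially observed issues contribute only their observed cells.

With M = 4 there are only B(4) = 15 partitions, so the posterior is computed
by exact enumeration in log space; the trial-by-trial allyship estimate for
an agent is the posterior probability that the agent shares the
participant's group. Unlike the similarity models, this estimate uses
within-trial information: the guess for the agent in position o of trial t
conditions on the participant's stance through trial t, all feedback through
trial t-1, and the trial-t feedback of agents guessed earlier in the trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from .similarity import ModulatorSeries
from .task import INDIVIDUALS, N_ISSUES, RunSchedule

DEFAULT_ALPHA = 2.0  # CRP dispersion used throughout
DEFAULT_GAMMA = 1.0  # Dirichlet concentration of the marginal likelihood


@dataclass(frozen=True)
class Partition:
    """A set partition in restricted-growth form: label z_i of individual i,
    with labels 0..K-1 and first occurrences in increasing order."""

    z: tuple[int, ...]

    def __post_init__(self) -> None:
        seen: list[int] = []
        for label in self.z:
            if label not in seen:
                if label != len(seen):
                    raise ValueError("labels must be in restricted-growth form")
                seen.append(label)

    @property
    def n_groups(self) -> int:
        return max(self.z) + 1

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(int(np.sum(np.array(self.z) == k)) for k in range(self.n_groups))

    def together(self, i: int, j: int) -> bool:
        return self.z[i] == self.z[j]


@lru_cache(maxsize=None)
def enumerate_partitions(m: int) -> tuple[Partition, ...]:
    """All set partitions of m items as restricted-growth strings, in
    lexicographic order. Exact enumeration is feasible for m <= 10."""
    if not 1 <= m <= 10:
        raise ValueError("m must lie in 1..10 for exact enumeration")
    out: list[Partition] = []

    def grow(prefix: list[int]) -> None:
        if len(prefix) == m:
            out.append(Partition(tuple(prefix)))
            return
        top = max(prefix, default=-1)
        for label in range(top + 2):
            grow(prefix + [label])

    grow([])
    return tuple(out)


def crp_log_prior(partition: Partition, alpha: float = DEFAULT_ALPHA) -> float:
    """Log CRP probability of a partition of M individuals."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    m = len(partition.z)
    return float(
        partition.n_groups * np.log(alpha)
        + gammaln(alpha)
        + sum(gammaln(t) for t in partition.sizes)
        - gammaln(m + alpha)
    )


def dm_log_likelihood(
    choices: np.ndarray,
    mask: np.ndarray,
    partition: Partition,
    gamma: float = DEFAULT_GAMMA,
    n_options: int = 2,
) -> float:
    """Log Dirichlet-multinomial marginal likelihood of observed choices.

    ``choices`` is an M x N integer table of options, ``mask`` a boolean
    M x N table marking which cells have been observed; unobserved cells
    contribute nothing. Group counts are computed per issue over the
    observed members only.
    """
    if gamma <= 0 or n_options < 2:
        raise ValueError("need gamma > 0 and n_options >= 2")
    choices = np.asarray(choices, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    if choices.shape != mask.shape or choices.shape[0] != len(partition.z):
        raise ValueError("choices/mask must be M x N with M matching the partition")
    if mask.any() and not ((choices[mask] >= 0) & (choices[mask] < n_options)).all():
        raise ValueError("observed choices must lie in 0..n_options-1")
    z = np.asarray(partition.z)
    total = 0.0
    for k in range(partition.n_groups):
        members = z == k
        obs = mask[members]  # members x issues
        ch = choices[members]
        t_kn = obs.sum(axis=0)  # observed group size per issue
        active = t_kn > 0
        if not active.any():
            continue
        total += float(
            (gammaln(n_options * gamma) - gammaln(t_kn[active] + n_options * gamma)).sum()
        )
        for c in range(n_options):
            l_knc = ((ch == c) & obs).sum(axis=0)
            total += float((gammaln(l_knc[active] + gamma) - gammaln(gamma)).sum())
    return total


@dataclass(frozen=True)
class PartitionPosterior:
    """Exact posterior over all partitions of the M individuals."""

    partitions: tuple[Partition, ...]
    log_prior: tuple[float, ...]
    log_lik: tuple[float, ...]
    posterior: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.posterior)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("posterior must be a normalized distribution")

    def argmax(self) -> Partition:
        return self.partitions[int(np.argmax(self.posterior))]


def partition_posterior(
    choices: np.ndarray,
    mask: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    gamma: float = DEFAULT_GAMMA,
    n_options: int = 2,
) -> PartitionPosterior:
    """Posterior over partitions via exact enumeration and log-sum-exp.

    ``mask=None`` treats every cell as observed. With no observed cells the
    posterior equals the CRP prior.
    """
    choices = np.asarray(choices, dtype=int)
    if mask is None:
        mask = np.ones_like(choices, dtype=bool)
    m = choices.shape[0]
    parts = enumerate_partitions(m)
    log_prior = np.array([crp_log_prior(p, alpha) for p in parts])
    log_lik = np.array(
        [dm_log_likelihood(choices, mask, p, gamma=gamma, n_options=n_options) for p in parts]
    )
    log_post = log_prior + log_lik
    post = np.exp(log_post - logsumexp(log_post))
    post = post / post.sum()
    return PartitionPosterior(
        partitions=parts,
        log_prior=tuple(log_prior),
        log_lik=tuple(log_lik),
        posterior=tuple(post),
    )


def comembership_prob(
    posterior: PartitionPosterior,
    a: str | int,
    b: str | int,
    method: str = "partition_sum",
) -> float:
    """Posterior probability that individuals a and b share a group.

    ``method="partition_sum"`` (default) sums posterior mass over partitions
    with z_a = z_b. ``method="marginal_product"`` instead multiplies the two
    independent marginals sum_k P(z_a=k) P(z_b=k); this ignores the posterior
    dependence between the assignments and is provided for comparison only.
    """
    ia = INDIVIDUALS.index(a) if isinstance(a, str) else int(a)
    ib = INDIVIDUALS.index(b) if isinstance(b, str) else int(b)
    if ia == ib:
        raise ValueError("co-membership requires two distinct individuals")
    post = np.asarray(posterior.posterior)
    if method == "partition_sum":
        keep = [p.together(ia, ib) for p in posterior.partitions]
        return float(post[keep].sum())
    if method == "marginal_product":
        k_max = max(p.n_groups for p in posterior.partitions)
        pa = np.zeros(k_max)
        pb = np.zeros(k_max)
        for p, w in zip(posterior.partitions, post):
            pa[p.z[ia]] += w
            pb[p.z[ib]] += w
        return float(pa @ pb)
    raise ValueError("method must be 'partition_sum' or 'marginal_product'")


def observation_mask(run: RunSchedule, t: int, position: int) -> np.ndarray:
    """Boolean 4 x 8 mask of what is known at the guess event for the agent
    in within-trial ``position`` (0-based) of 1-based trial ``t``.

    Known: the participant's stances on issues 1..t, all agents' feedback on
    issues 1..t-1, and the trial-t feedback of agents guessed earlier in the
    trial. The guessed-about agent's own trial-t choice is never included
    (feedback arrives after the guess).
    """
    if not 1 <= t <= N_ISSUES or not 0 <= position <= 2:
        raise ValueError("t in 1..8 and position in 0..2 required")
    mask = np.zeros((4, N_ISSUES), dtype=bool)
    mask[0, :t] = True  # participant answers before guessing
    mask[1:, : t - 1] = True  # completed issues, all agents
    for agent in run.agent_order_per_trial[t - 1][:position]:
        mask[INDIVIDUALS.index(agent), t - 1] = True
    return mask


def latent_series(
    run: RunSchedule,
    alpha: float = DEFAULT_ALPHA,
    gamma: float = DEFAULT_GAMMA,
    method: str = "partition_sum",
) -> ModulatorSeries:
    """Trial-by-trial P(agent shares the participant's group) for every
    guess event of a run, sequentially conditioning on all feedback observed
    so far (including earlier guesses within the same trial)."""
    choices = run.choice_matrix()
    values, events = [], []
    for t in range(1, N_ISSUES + 1):
        for position, agent in enumerate(run.agent_order_per_trial[t - 1]):
            mask = observation_mask(run, t, position)
            post = partition_posterior(choices, mask, alpha=alpha, gamma=gamma)
            values.append(comembership_prob(post, "P", agent, method=method))
            events.append((t, agent))
    return ModulatorSeries("latent", run.run_id, tuple(values), tuple(events))


def endpoint_comembership(
    run: RunSchedule,
    agent: str,
    alpha: float = DEFAULT_ALPHA,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """P(agent shares the participant's group) after all 8 issues."""
    post = partition_posterior(run.choice_matrix(), alpha=alpha, gamma=gamma)
    return comembership_prob(post, "P", agent)
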