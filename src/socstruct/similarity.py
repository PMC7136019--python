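"""Dyadic similarity and feature similarity-over-agents.

Dyadic similarity S_d between two individuals is the Laplace-smoothed
proportion of completed issues on which they agreed:

    S_d(t) = (k + 1) / (t + 1)

with t the 1-based index of the current trial and k the number of agreements
on trials 1..t-1, so every pair starts at 0.50. Feature similarity S_f is
second-order: the Pearson correlation between two individuals' rows of the
4 x 4 dyadic-similarity matrix over {P, A, B, C}, affinely rescaled from
[-1, 1] to (0, 1) and passed through a log-odds transform.

Both models produce one parametric-modulator value per guess event (8 trials
x 3 agents = 24 per run), ordered by trial and within-trial agent order.
Neither model uses any within-trial feedback: all three agents' values at
trial t depend only on issues 1..t-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import INDIVIDUALS, N_ISSUES, RunSchedule


@dataclass(frozen=True)
class ModulatorSeries:
    """Per-run parametric-modulator values, one per guess event.

    ``events[i] = (trial, agent)`` with 1-based trials; ``values[i]`` is the
    model's allyship estimate for that guess. Dyadic and latent values live
    in (0, 1); feature values are on the log-odds scale.
    """

    model: str
    run_id: int
    values: tuple[float, ...]
    events: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.events):
            raise ValueError("one value per guess event required")
        if len(self.values) != 3 * N_ISSUES:
            raise ValueError("a run has 24 guess events")
        if not np.isfinite(self.values).all():
            raise ValueError("modulator values must be finite")

    def to_frame(self, participant: str = "NA") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": participant,
                "run": self.run_id,
                "trial": [t for t, _ in self.events],
                "agent": [a for _, a in self.events],
                "model": self.model,
                "value": self.values,
            }
        )


def dyadic_similarity(k_agreements: int, t: int) -> float:
    """S_d after ``k_agreements`` agreements in the first ``t - 1`` trials.

    Equals 0.50 at t=1 (no history) and approaches the empirical agreement
    rate as trials accumulate.
    """
    if t < 1:
        raise ValueError("t is a 1-based trial index")
    if not 0 <= k_agreements <= t - 1:
        raise ValueError(
            f"invalid history: {k_agreements} agreements in {t - 1} completed trials"
        )
    return (k_agreements + 1) / (t + 1)


def _pair_agreements(run: RunSchedule, i: str, j: str, upto: int) -> int:
    """Agreements between individuals i, j on issues 1..upto (0 = none)."""
    mat = run.choice_matrix()
    xi = mat[INDIVIDUALS.index(i), :upto]
    xj = mat[INDIVIDUALS.index(j), :upto]
    return int((xi == xj).sum())


def dyadic_series(run: RunSchedule) -> ModulatorSeries:
    """Participant-agent S_d for every guess event of a run.

    The value for agent j at trial t uses only the participant-j agreement
    history on issues 1..t-1; within a trial all agents share the same t.
    """
    values, events = [], []
    for t in range(1, N_ISSUES + 1):
        for agent in run.agent_order_per_trial[t - 1]:
            k = _pair_agreements(run, "P", agent, t - 1)
            values.append(dyadic_similarity(k, t))
            events.append((t, agent))
    return ModulatorSeries("dyadic", run.run_id, tuple(values), tuple(events))


def build_similarity_matrix(run: RunSchedule, t: int) -> np.ndarray:
    """4 x 4 dyadic-similarity matrix over (P, A, B, C) entering trial t.

    Off-diagonal entries are S_d on issues 1..t-1; the diagonal is exactly 1.
    """
    if t < 1:
        raise ValueError("t is a 1-based trial index")
    m = np.eye(4)
    for i in range(4):
        for j in range(i + 1, 4):
            k = _pair_agreements(run, INDIVIDUALS[i], INDIVIDUALS[j], t - 1)
            m[i, j] = m[j, i] = dyadic_similarity(k, t)
    return m


def feature_similarity(matrix: np.ndarray, agent: str, eps: float = 1e-3) -> float:
    """Log-odds feature similarity between the participant and ``agent``.

    Pearson-correlates the participant's and the agent's full rows of the
    similarity matrix (all four columns, diagonal included), rescales
    r -> (r + 1)/2, clips to [eps, 1 - eps] and returns the log-odds.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("similarity matrix must be 4 x 4 over (P, A, B, C)")
    row_p = matrix[INDIVIDUALS.index("P")]
    row_a = matrix[INDIVIDUALS.index(agent)]
    if np.ptp(row_p) == 0 or np.ptp(row_a) == 0:
        raise ValueError("zero-variance similarity row: correlation undefined")
    r = float(np.corrcoef(row_p, row_a)[0, 1])
    s_f = np.clip((r + 1.0) / 2.0, eps, 1.0 - eps)
    return float(np.log(s_f) - np.log1p(-s_f))


def feature_series(run: RunSchedule, eps: float = 1e-3) -> ModulatorSeries:
    """Feature similarity-over-agents for every guess event of a run.

    The matrix entering trial t is built from completed issues only; like
    the dyadic model, this model does no within-trial updating.
    """
    values, events = [], []
    for t in range(1, N_ISSUES + 1):
        m = build_similarity_matrix(run, t)
        for agent in run.agent_order_per_trial[t - 1]:
            values.append(feature_similarity(m, agent, eps=eps))
            events.append((t, agent))
    return ModulatorSeries("feature", run.run_id, tuple(values), tuple(events))


def modulator_frame(series: list[ModulatorSeries], participant: str = "NA") -> pd.DataFrame:
    """Stack modulator series into one tidy frame."""
    return pd.concat([s.to_frame(participant) for s in series], ignore_index=True)
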