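"""Synthetic ally-learning task sessions.

A session consists of six runs. In each run the participant states their own
stance on eight binary political issues and learns, issue by issue, the
stances of three novel agents (A, B, C). The inter-agent agreement structure
is fixed by design: A's stances are the elementwise inverse of B's (0/8
agreement), B and C agree on exactly 5 of 8 issues, and consequently A and C
agree on exactly 3 of 8. Each run ends with an ally-choice trial in which the
participant aligns with either Agent A or Agent B on an unknown issue.

Participant-agent agreement varies freely across runs unless a target
agreement pattern is requested (as in the high-C / low-C behavioral designs,
where B agrees with the participant on 4/8 issues and C on 7/8 or 1/8).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

AGENTS: tuple[str, ...] = ("A", "B", "C")
INDIVIDUALS: tuple[str, ...] = ("P", "A", "B", "C")
N_ISSUES = 8
N_RUNS = 6

#: fixed inter-agent agreement counts (pairs of agents, out of 8 issues)
INTER_AGENT_AGREEMENT: dict[tuple[str, str], int] = {
    ("A", "B"): 0,
    ("B", "C"): 5,
    ("A", "C"): 3,
}


class InfeasiblePatternError(ValueError):
    """Requested participant-agreement pattern conflicts with the fixed
    inter-agent structure; the message names the violated constraint."""


def agreement(x: np.ndarray, y: np.ndarray) -> int:
    """Number of issues on which two binary stance vectors coincide."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("stance vectors must have equal length")
    return int((x == y).sum())


@dataclass(frozen=True)
class RunSchedule:
    """One run: participant stance plus the three agents' choices.

    ``agent_choices`` rows are ordered (A, B, C). ``agent_order_per_trial``
    gives the within-trial guess order of the agents for each of the eight
    learning trials; ``allychoice_photo_order`` the order in which the A/B
    photos precede the ally-choice trial.
    """

    run_id: int
    issues: tuple[str, ...]
    participant_stance: tuple[int, ...]
    agent_choices: tuple[tuple[int, ...], ...]
    agent_order_per_trial: tuple[tuple[str, str, str], ...]
    allychoice_photo_order: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.issues) != N_ISSUES or len(set(self.issues)) != N_ISSUES:
            raise ValueError("a run needs 8 distinct issues")
        choices = self.choice_matrix()
        if not np.isin(choices, (0, 1)).all():
            raise ValueError("choices must be binary")
        a, b, c = (self.agent_stance(x) for x in AGENTS)
        if agreement(a, b) != 0:
            raise ValueError("Agent A must be Agent B's elementwise inverse")
        if agreement(b, c) != INTER_AGENT_AGREEMENT[("B", "C")]:
            raise ValueError("Agents B and C must agree on exactly 5 issues")
        if agreement(a, c) != INTER_AGENT_AGREEMENT[("A", "C")]:
            raise ValueError("Agents A and C must agree on exactly 3 issues")
        if len(self.agent_order_per_trial) != N_ISSUES or any(
            sorted(order) != sorted(AGENTS) for order in self.agent_order_per_trial
        ):
            raise ValueError("need one (A,B,C) permutation per trial")
        if sorted(self.allychoice_photo_order) != ["A", "B"]:
            raise ValueError("photo order must be a permutation of (A, B)")

    def agent_stance(self, agent: str) -> np.ndarray:
        return np.asarray(self.agent_choices[AGENTS.index(agent)])

    def choice_matrix(self) -> np.ndarray:
        """4 x 8 matrix of stances, rows ordered (P, A, B, C)."""
        return np.vstack(
            [np.asarray(self.participant_stance)] + [np.asarray(r) for r in self.agent_choices]
        )

    def participant_agreement(self, agent: str) -> int:
        return agreement(np.asarray(self.participant_stance), self.agent_stance(agent))


@dataclass(frozen=True)
class TaskSession:
    """Six runs for one participant; issues and agents are novel per run."""

    participant_id: str
    runs: tuple[RunSchedule, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.runs) != N_RUNS:
            raise ValueError("a session has exactly 6 runs")
        all_issues = [i for r in self.runs for i in r.issues]
        if len(set(all_issues)) != N_RUNS * N_ISSUES:
            raise ValueError("issues must be disjoint across runs")


@dataclass(frozen=True)
class BehavioralDesign:
    """A run with the fixed participant-agreement pattern of the N=333
    behavioral design: B (and hence A) at 4/8, C at 7/8 (high_C) or 1/8
    (low_C)."""

    condition: str
    schedule: RunSchedule

    def __post_init__(self) -> None:
        if self.condition not in ("high_C", "low_C"):
            raise ValueError("condition must be 'high_C' or 'low_C'")
        want_c = 7 if self.condition == "high_C" else 1
        if self.schedule.participant_agreement("B") != 4:
            raise ValueError("Agent B must agree with the participant on 4/8 issues")
        if self.schedule.participant_agreement("C") != want_c:
            raise ValueError(f"Agent C must agree on {want_c}/8 issues")


def _all_binary_columns(n: int = N_ISSUES) -> np.ndarray:
    """All 2^n binary vectors of length n, as an array of shape (2^n, n)."""
    return np.array(list(itertools.product((0, 1), repeat=n)), dtype=int)


def _feasible_c_columns(
    b_col: np.ndarray, stance: np.ndarray, c_agreement: int | None
) -> np.ndarray:
    cols = _all_binary_columns()
    keep = (cols == b_col).sum(axis=1) == INTER_AGENT_AGREEMENT[("B", "C")]
    if c_agreement is not None:
        keep &= (cols == stance).sum(axis=1) == c_agreement
    return cols[keep]


def _normalize_pattern(pattern) -> dict[str, int]:
    if pattern is None:
        return {}
    if isinstance(pattern, Mapping):
        out = {str(k): int(v) for k, v in pattern.items()}
    else:  # (A, B, C) triple; None entries unconstrained
        out = {a: int(v) for a, v in zip(AGENTS, pattern) if v is not None}
    unknown = set(out) - set(AGENTS)
    if unknown:
        raise ValueError(f"unknown agents in pattern: {sorted(unknown)}")
    if any(not 0 <= v <= N_ISSUES for v in out.values()):
        raise InfeasiblePatternError("agreement counts must lie in 0..8")
    return out


def generate_run_schedule(
    seed: int | np.random.Generator,
    pattern: Mapping[str, int] | Sequence[int | None] | None = None,
    run_id: int = 0,
    issues: Iterable[str] | None = None,
    stance_p: float = 0.5,
) -> RunSchedule:
    """Sample a run uniformly from the set satisfying the agreement structure.

    B's stances are drawn uniformly (optionally constrained to a requested
    participant-agreement count), A is set to B's inverse, and C is drawn
    uniformly from the (enumerated) set of columns agreeing with B on 5/8
    issues and matching any requested participant-agreement count.

    Parameters
    ----------
    pattern
        Optional target participant-agent agreement counts, either a mapping
        like ``{"B": 4, "C": 7}`` or an ``(A, B, C)`` triple with ``None``
        for unconstrained entries. Infeasible requests raise
        :class:`InfeasiblePatternError` naming the violated constraint.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    want = _normalize_pattern(pattern)
    if "A" in want and "B" in want and want["A"] + want["B"] != N_ISSUES:
        raise InfeasiblePatternError(
            "A is B's inverse, so agreement(A,P) + agreement(B,P) must equal 8; "
            f"got {want['A']} + {want['B']}"
        )
    if "A" in want and "B" not in want:
        want["B"] = N_ISSUES - want.pop("A")

    stance = (rng.random(N_ISSUES) < stance_p).astype(int)
    if "B" in want:
        agree_idx = rng.choice(N_ISSUES, size=want["B"], replace=False)
        b = 1 - stance
        b[agree_idx] = stance[agree_idx]
    else:
        b = rng.integers(0, 2, N_ISSUES)
    a = 1 - b
    c_cands = _feasible_c_columns(b, stance, want.get("C"))
    if len(c_cands) == 0:
        raise InfeasiblePatternError(
            f"no Agent C column agrees with B on 5/8 issues while agreeing with "
            f"the participant on {want.get('C')}/8 (given agreement(B,P)="
            f"{agreement(b, stance)})"
        )
    c = c_cands[rng.integers(len(c_cands))]

    if issues is None:
        issues = tuple(f"issue_{run_id:02d}_{i:02d}" for i in range(N_ISSUES))
    orders = tuple(tuple(rng.permutation(AGENTS)) for _ in range(N_ISSUES))
    photo_order = tuple(rng.permutation(("A", "B")))
    return RunSchedule(
        run_id=run_id,
        issues=tuple(issues),
        participant_stance=tuple(int(x) for x in stance),
        agent_choices=(tuple(int(x) for x in a), tuple(int(x) for x in b), tuple(int(x) for x in c)),
        agent_order_per_trial=orders,
        allychoice_photo_order=photo_order,
    )


def generate_behavioral_design(condition: str, seed: int | np.random.Generator) -> BehavioralDesign:
    """A run with the behavioral-design agreement pattern: B at 4/8, C at 7/8
    (``high_C``) or 1/8 (``low_C``)."""
    if condition not in ("high_C", "low_C"):
        raise ValueError("condition must be 'high_C' or 'low_C'")
    c_count = 7 if condition == "high_C" else 1
    schedule = generate_run_schedule(seed, pattern={"B": 4, "C": c_count})
    return BehavioralDesign(condition=condition, schedule=schedule)


def simulate_session(
    participant_id: str,
    seed: int,
    stance_p: float = 0.5,
    patterns: Sequence[Mapping[str, int] | None] | None = None,
) -> TaskSession:
    """Simulate a full six-run session with i.i.d. Bernoulli(``stance_p``)
    participant stances and disjoint issues/agents per run."""
    if not 0.0 < stance_p < 1.0:
        raise ValueError("stance_p must lie strictly between 0 and 1")
    if patterns is not None and len(patterns) != N_RUNS:
        raise ValueError("need one pattern (or None) per run")
    rng = np.random.default_rng(seed)
    runs = tuple(
        generate_run_schedule(
            rng,
            pattern=None if patterns is None else patterns[r],
            run_id=r,
            issues=tuple(f"{participant_id}_r{r}_i{i:02d}" for i in range(N_ISSUES)),
            stance_p=stance_p,
        )
        for r in range(N_RUNS)
    )
    return TaskSession(participant_id=participant_id, runs=runs, seed=int(seed))


def simulate_ally_choices(
    session: TaskSession,
    coeffs: Sequence[float],
    coding: str = "count",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one ally-choice per run from a logistic choice rule.

    ``coeffs = (intercept, b_B, b_C, b_BxC)`` act on Agent B's and Agent C's
    agreement with the participant, coded either as raw counts 0-8
    (``coding="count"``) or proportions 0-1 (``coding="proportion"``).

    Returns a tidy frame with one row per run: ``participant, run, chose_B,
    agree_B, agree_C`` (agreements on the chosen coding scale).
    """
    if coding not in ("count", "proportion"):
        raise ValueError("coding must be 'count' or 'proportion'")
    if len(coeffs) != 4:
        raise ValueError("coeffs must be (intercept, b_B, b_C, b_BxC)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c0, b_b, b_c, b_bc = (float(x) for x in coeffs)
    scale = 1.0 if coding == "count" else 1.0 / N_ISSUES
    rows = []
    for run in session.runs:
        x_b = run.participant_agreement("B") * scale
        x_c = run.participant_agreement("C") * scale
        p = expit(c0 + b_b * x_b + b_c * x_c + b_bc * x_b * x_c)
        rows.append(
            {
                "participant": session.participant_id,
                "run": run.run_id,
                "chose_B": int(rng.random() < p),
                "agree_B": x_b,
                "agree_C": x_c,
            }
        )
    return pd.DataFrame(rows)


def event_table(session: TaskSession) -> pd.DataFrame:
    """Tidy event listing (no onsets) for a session: one row per event with
    columns (participant, run, trial, event_type, agent, issue, choice).

    Onsets are assigned by the design-matrix timing rules in
    :mod:`socstruct.neural`.
    """
    rows = []
    for run in session.runs:
        for t in range(N_ISSUES):
            issue = run.issues[t]
            rows.append(
                dict(
                    participant=session.participant_id,
                    run=run.run_id,
                    trial=t + 1,
                    event_type="self_choice",
                    agent="NA",
                    issue=issue,
                    choice=run.participant_stance[t],
                )
            )
            for agent in run.agent_order_per_trial[t]:
                choice = int(run.agent_stance(agent)[t])
                for etype in ("guess", "feedback"):
                    rows.append(
                        dict(
                            participant=session.participant_id,
                            run=run.run_id,
                            trial=t + 1,
                            event_type=etype,
                            agent=agent,
                            issue=issue,
                            choice=choice,
                        )
                    )
        for agent in run.allychoice_photo_order:
            rows.append(
                dict(
                    participant=session.participant_id,
                    run=run.run_id,
                    trial=N_ISSUES + 1,
                    event_type="photo",
                    agent=agent,
                    issue="NA",
                    choice=-1,
                )
            )
        rows.append(
            dict(
                participant=session.participant_id,
                run=run.run_id,
                trial=N_ISSUES + 1,
                event_type="ally_choice",
                agent="NA",
                issue="NA",
                choice=-1,
            )
        )
    return pd.DataFrame(rows)
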