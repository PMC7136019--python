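import itertools

import numpy as np
import pytest

from socstruct import task


@pytest.fixture(scope="session")
def example_run() -> task.RunSchedule:
    return task.generate_run_schedule(seed=7)


@pytest.fixture(scope="session")
def example_session() -> task.TaskSession:
    return task.simulate_session("sub00", seed=11)


@pytest.fixture(scope="session")
def high_c_design() -> task.BehavioralDesign:
    return task.generate_behavioral_design("high_C", seed=21)


@pytest.fixture(scope="session")
def low_c_design() -> task.BehavioralDesign:
    return task.generate_behavioral_design("low_C", seed=21)


def brute_force_agreements(choices: np.ndarray) -> dict[tuple[str, str], int]:
    """Independent agreement counter over all pairs of (P, A, B, C) rows."""
    names = ("P", "A", "B", "C")
    out = {}
    for i, j in itertools.combinations(range(4), 2):
        out[(names[i], names[j])] = int((choices[i] == choices[j]).sum())
    return out


def enumerate_set_partitions(items: tuple) -> list[list[set]]:
    """Independent set-partition enumerator (recursive, frozenset blocks)."""
    if not items:
        return [[]]
    head, rest = items[0], items[1:]
    result = []
    for sub in enumerate_set_partitions(rest):
        for i in range(len(sub)):
            grown = [set(b) for b in sub]
            grown[i].add(head)
            result.append(grown)
        result.append([{head}] + [set(b) for b in sub])
    return result
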