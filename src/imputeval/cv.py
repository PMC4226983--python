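"""Five-fold cross-validation design and reference-set scenarios.

Individuals are partitioned into five near-equal groups; each group
serves as the validation set once.  The reference set for a fold depends
on the scenario:

* ``S80`` — all four remaining groups (80% of individuals),
* ``S60`` — the three cyclically following groups (60%),
* ``S40`` — the two cyclically following groups (40%),
* ``TWO_STEP`` — the two following groups impute the low-density panel
  up to the intermediate panel (step 1) and the two preceding groups
  impute on to sequence density (step 2); the two reference sets are
  disjoint.

"Following" and "preceding" wrap around group 5 -> group 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCENARIOS",
    "GroupAssignment",
    "Fold",
    "ScenarioPlan",
    "assign_groups",
    "scenario_references",
    "build_plan",
]

SCENARIOS = ("S80", "S60", "S40", "TWO_STEP")


@dataclass
class GroupAssignment:
    """Mapping individual id -> group label in 1..k."""

    group_of: dict[str, int]
    k: int
    seed: int

    def members(self, group: int) -> list[str]:
        return [i for i, g in self.group_of.items() if g == group]

    def group_sizes(self) -> dict[int, int]:
        sizes = {g: 0 for g in range(1, self.k + 1)}
        for g in self.group_of.values():
            sizes[g] += 1
        return sizes


@dataclass
class Fold:
    validation_group: int
    reference_groups: tuple[int, ...] = ()
    step1_reference_groups: tuple[int, ...] = ()
    step2_reference_groups: tuple[int, ...] = ()


@dataclass
class ScenarioPlan:
    scenario: str
    folds: list[Fold] = field(default_factory=list)


def assign_groups(
    individual_ids: list[str], k: int = 5, seed: int = 0
) -> GroupAssignment:
    """Uniform random partition into ``k`` groups of near-equal size.

    Group sizes differ by at most one; the assignment is a deterministic
    function of the id order and the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(individual_ids) < k:
        raise ValueError(
            f"need at least {k} individuals, got {len(individual_ids)}"
        )
    if len(set(individual_ids)) != len(individual_ids):
        raise ValueError("individual ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(individual_ids))
    group_of: dict[str, int] = {}
    for rank, idx in enumerate(order):
        group_of[individual_ids[idx]] = (rank % k) + 1
    return GroupAssignment(group_of=group_of, k=k, seed=seed)


def _cyc(group: int, offset: int, k: int = 5) -> int:
    return (group - 1 + offset) % k + 1


def scenario_references(scenario: str, validation_group: int, k: int = 5):
    """Reference groups for one fold of a scenario.

    Returns a tuple of group labels for the single-step scenarios, or a
    ``(step1, step2)`` pair of tuples for ``TWO_STEP``.
    """
    if not (1 <= validation_group <= k):
        raise ValueError(f"validation_group must be in 1..{k}")
    v = validation_group
    if scenario == "S80":
        return tuple(_cyc(v, off, k) for off in range(1, k))
    if scenario == "S60":
        return tuple(_cyc(v, off, k) for off in (1, 2, 3))
    if scenario == "S40":
        return tuple(_cyc(v, off, k) for off in (1, 2))
    if scenario == "TWO_STEP":
        step1 = tuple(_cyc(v, off, k) for off in (1, 2))
        step2 = tuple(_cyc(v, off, k) for off in (-2, -1))
        return step1, step2
    raise ValueError(f"unknown scenario {scenario!r}")


def build_plan(scenario: str, k: int = 5) -> ScenarioPlan:
    """Full plan: one fold per validation group, in label order."""
    folds = []
    for v in range(1, k + 1):
        refs = scenario_references(scenario, v, k)
        if scenario == "TWO_STEP":
            step1, step2 = refs
            folds.append(
                Fold(
                    validation_group=v,
                    step1_reference_groups=step1,
                    step2_reference_groups=step2,
                )
            )
        else:
            folds.append(Fold(validation_group=v, reference_groups=refs))
    return ScenarioPlan(scenario=scenario, folds=folds)
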