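"""Per-cycle lab behaviour and the evolutionary death-birth step.

The research world is a fixed population of 100 competing labs.  Each
research cycle every lab may take on and test one new hypothesis; every
tested hypothesis is written up and published as a paper, and positive
results -- true or false -- earn the pay-off that drives selection.  At
the end of the cycle one old lab retires (the oldest of a random sample)
and one successful lab (the highest pay-off of a random sample) founds a
child that inherits its effort, with rare Gaussian mutation.

Effort ``e`` in [1, 100] is the quantity/quality dial: low effort means
more hypotheses tackled per cycle but a higher false-positive
probability ``alpha = W / (1 + (1 - W) e)`` where ``W`` is statistical
power.  Selection on pay-off therefore favours low effort, which is the
engine of the competitive spiral.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "WorldParams",
    "LabState",
    "WorldState",
    "CycleOutcome",
    "prob_new_hypothesis",
    "false_positive_prob",
    "simulate_lab_cycle",
    "make_child",
    "evolve_population",
    "run_cycle",
]


def prob_new_hypothesis(effort, eta: float):
    """Probability that a lab takes on a new hypothesis this cycle.

    Low-effort labs spend less time per hypothesis and therefore start
    new ones more often::

        p = 1 - eta * log10(e)

    Parameters
    ----------
    effort : float or array-like
        Lab effort, in [1, 100].
    eta : float
        Strength of the effort/output trade-off.  Must satisfy
        ``eta * log10(100) <= 1`` so the probability stays positive.

    Returns
    -------
    float or ndarray in (0, 1].
    """
    e = np.asarray(effort, dtype=float)
    if np.any((e < 1.0) | (e > 100.0)):
        raise ValueError("effort must lie in [1, 100]")
    if eta * math.log10(100.0) > 1.0:
        raise ValueError("eta too large: tackling probability would be negative at e=100")
    p = 1.0 - eta * np.log10(e)
    return float(p) if np.ndim(effort) == 0 else p


def false_positive_prob(power, effort):
    """False-positive probability ``alpha = W / (1 + (1 - W) e)``.

    Strictly decreasing in effort for ``W < 1``: at ``W = 0.8`` it runs
    from 0.6667 at ``e = 1`` down to 0.0381 at ``e = 100``, and equals
    the conventional 0.05 at ``e = 75``.
    """
    w = np.asarray(power, dtype=float)
    e = np.asarray(effort, dtype=float)
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("power must lie in [0, 1]")
    if np.any(e < 1.0):
        raise ValueError("effort must be >= 1")
    a = w / (1.0 + (1.0 - w) * e)
    if np.ndim(power) == 0 and np.ndim(effort) == 0:
        return float(a)
    return a


@dataclass(frozen=True)
class WorldParams:
    """Structural constants of the research world.

    Defaults are the baseline: 100 labs, ``eta = 0.2``, power 0.8,
    initial effort 75 (so every lab starts at alpha = 0.05), hypotheses
    true with prior 0.1, inheritance mutated with probability 0.01 by a
    N(0, 1) offset, and a detectable mistake planted in a quarter of
    false-positive papers.
    """

    population_size: int = 100
    eta: float = 0.2
    truth_prior: float = 0.1
    power: float = 0.8
    initial_effort: float = 75.0
    mutation_prob: float = 0.01
    mutation_sd: float = 1.0
    mistake_prob: float = 0.25
    death_sample: int = 10
    birth_sample: int = 10
    payoff_per_positive: float = 1.0

    def __post_init__(self) -> None:
        for name in ("truth_prior", "power", "mutation_prob", "mistake_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if not 1.0 <= self.initial_effort <= 100.0:
            raise ValueError(f"initial_effort must lie in [1, 100], got {self.initial_effort}")
        if self.eta < 0 or self.eta * math.log10(100.0) > 1.0:
            raise ValueError(f"eta must lie in [0, 0.5], got {self.eta}")
        if self.population_size < self.death_sample:
            raise ValueError("population_size must be >= death_sample")
        if self.population_size < self.birth_sample + 1:
            raise ValueError("population_size must be >= birth_sample + 1")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be non-negative")
        if self.payoff_per_positive <= 0:
            raise ValueError("payoff_per_positive must be positive")


@dataclass
class LabState:
    """One lab: heritable effort plus its accumulated publication record."""

    id: int
    effort: float
    power: float = 0.8
    birth_cycle: int = 0
    payoff: float = 0.0
    papers: int = 0
    false_positives: int = 0
    mistakes: int = 0
    parent_id: Optional[int] = None
    child_ids: set = field(default_factory=set)
    audited: bool = False

    def age(self, cycle: int) -> int:
        return cycle - self.birth_cycle


@dataclass(frozen=True)
class CycleOutcome:
    """What one lab did in one research cycle."""

    tackled: bool
    hypothesis_true: Optional[bool]
    positive: Optional[bool]
    published: bool
    false_positive: bool
    mistake: bool


class WorldState:
    """The full research world: the living labs plus lifetime totals.

    Cumulative totals (`total_papers` and friends) cover everything ever
    produced in the run, including by labs later removed by retirement
    or by an audit.
    """

    def __init__(self, params: WorldParams, labs: Optional[list] = None):
        self.params = params
        self.cycle = 0
        if labs is None:
            labs = [
                LabState(id=i, effort=params.initial_effort, power=params.power)
                for i in range(params.population_size)
            ]
        self.labs = labs
        self.next_id = max(l.id for l in labs) + 1
        self.parent_of = {l.id: l.parent_id for l in labs}
        self.audited_ever: set = set()
        # lifetime world totals (monotone non-decreasing)
        self.total_papers = 0
        self.total_false_positives = 0
        self.total_mistakes = 0
        self.total_audits = 0
        self.total_skipped_audits = 0
        self.total_removals = 0
        self.total_audit_cost = 0.0
        self.total_audited_papers = 0

    # -- convenience ---------------------------------------------------
    def lab_by_id(self, lab_id: int) -> Optional[LabState]:
        for lab in self.labs:
            if lab.id == lab_id:
                return lab
        return None

    def mean_effort(self) -> float:
        return float(np.mean([l.effort for l in self.labs]))

    def mean_alpha(self) -> float:
        e = np.array([l.effort for l in self.labs])
        return float(np.mean(false_positive_prob(self.params.power, e)))

    def register_birth(self, child: LabState) -> None:
        self.parent_of[child.id] = child.parent_id


def simulate_lab_cycle(lab: LabState, params: WorldParams, rng) -> CycleOutcome:
    """One lab's research for one cycle; mutates ``lab`` in place.

    With probability ``1 - eta log10(e)`` the lab tackles a hypothesis,
    true with the field-wide prior.  A true hypothesis tests positive
    with probability ``W``; a false one with probability ``alpha``.
    Every tested hypothesis is published; positive results earn the
    pay-off; a false positive carries a detectable mistake with
    probability ``mistake_prob``.
    """
    p_tackle = prob_new_hypothesis(lab.effort, params.eta)
    if rng.random() >= p_tackle:
        return CycleOutcome(False, None, None, False, False, False)
    hypothesis_true = rng.random() < params.truth_prior
    p_pos = params.power if hypothesis_true else false_positive_prob(params.power, lab.effort)
    positive = rng.random() < p_pos
    fp = positive and not hypothesis_true
    mistake = bool(fp and rng.random() < params.mistake_prob)
    lab.papers += 1
    if positive:
        lab.payoff += params.payoff_per_positive
    if fp:
        lab.false_positives += 1
    if mistake:
        lab.mistakes += 1
    return CycleOutcome(True, hypothesis_true, positive, True, fp, mistake)


def make_child(parent: LabState, params: WorldParams, rng, *,
               birth_cycle: int = 0, lab_id: Optional[int] = None) -> LabState:
    """Found a child lab inheriting the parent's effort.

    With probability ``mutation_prob`` the inherited effort is offset by
    a draw from N(0, ``mutation_sd``); the result is clamped to
    [1, 100].  The child starts with an empty record.
    """
    effort = parent.effort
    if rng.random() < params.mutation_prob:
        effort = float(min(max(effort + rng.normal(0.0, params.mutation_sd), 1.0), 100.0))
    child = LabState(
        id=parent.id + 1 if lab_id is None else lab_id,
        effort=effort,
        power=parent.power,
        birth_cycle=birth_cycle,
        parent_id=parent.id,
    )
    parent.child_ids.add(child.id)
    return child


def _argmax_random_tie(values, rng) -> int:
    mx = max(values)
    cand = [i for i, v in enumerate(values) if v == mx]
    if len(cand) == 1:
        return cand[0]
    return cand[int(rng.integers(len(cand)))]


def evolve_population(state: WorldState, params: WorldParams, rng) -> WorldState:
    """One death-birth step: the oldest of a random 10 dies, the richest
    of a random 10 survivors reproduces.  Ties broken uniformly."""
    labs = state.labs
    idx = rng.choice(len(labs), size=params.death_sample, replace=False)
    ages = [labs[i].age(state.cycle) for i in idx]
    dead_pos = int(idx[_argmax_random_tie(ages, rng)])
    labs.pop(dead_pos)

    jdx = rng.choice(len(labs), size=params.birth_sample, replace=False)
    pays = [labs[j].payoff for j in jdx]
    parent = labs[int(jdx[_argmax_random_tie(pays, rng)])]
    child = make_child(parent, params, rng, birth_cycle=state.cycle, lab_id=state.next_id)
    state.next_id += 1
    labs.append(child)
    state.register_birth(child)
    return state


def run_cycle(state: WorldState, params: WorldParams, rng,
              policy=None, cost_model=None):
    """One full research cycle: all labs act, then death-birth, then
    (if scheduled) one audit.  Returns the audit record, if any."""
    from .audit import conduct_audit, is_audit_cycle  # local import: avoids cycle

    state.cycle += 1
    for lab in state.labs:
        out = simulate_lab_cycle(lab, params, rng)
        state.total_papers += int(out.published)
        state.total_false_positives += int(out.false_positive)
        state.total_mistakes += int(out.mistake)
    evolve_population(state, params, rng)
    record = None
    if policy is not None and is_audit_cycle(state.cycle, policy):
        record = conduct_audit(state, policy, params, cost_model, rng)
    return record
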