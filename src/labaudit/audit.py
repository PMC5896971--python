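"""Random audits: scheduling, eligibility, statistics, removal, boosts.

After a burn-in, an audit runs every ``j`` cycles.  One never-audited
lab with at least ``n`` papers is drawn at random and its cumulative
record is inspected.  Labs whose audit statistic falls in the top third
of the current population distribution are removed and replaced; labs
that survive the audit -- and the parents and children of the audited
lab -- raise their effort, which is where most of the benefit of
auditing comes from.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import (
    LabState,
    WorldParams,
    WorldState,
    _argmax_random_tie,
    false_positive_prob,
    make_child,
)
from .economics import CostModel, audit_cost

__all__ = [
    "AuditPolicy",
    "AuditRecord",
    "AUDIT_STATISTICS",
    "is_audit_cycle",
    "eligible_labs",
    "audit_statistic",
    "apply_reviewer_noise",
    "compute_cutoff",
    "conduct_audit",
]

AUDIT_STATISTICS = ("false_positive_proportion", "alpha", "mistake_proportion")

#: floor applied to the removal cut-off for false-positive based audits,
#: so labs are never removed for a rate an ideal lab could show.
DEFAULT_FP_CUTOFF_FLOOR = 0.05


@dataclass(frozen=True)
class AuditPolicy:
    """Audit schedule, eligibility, statistic and consequences.

    ``cutoff_floor=None`` resolves to 0.05 for false-positive based
    statistics and to 0 for mistake-proportion audits.  A
    ``cutoff_percentile`` of 1.0 means no lab is ever removed.
    """

    enabled: bool = True
    cycles_per_audit: int = 75
    burn_in: int = 100
    min_papers: int = 50
    statistic: str = "false_positive_proportion"
    cutoff_percentile: float = 0.67
    cutoff_floor: Optional[float] = None
    review_error_pct: float = 0.0
    effort_boost_audited: float = 5.0
    effort_boost_network: float = 5.0

    def __post_init__(self) -> None:
        if self.cycles_per_audit < 1:
            raise ValueError("cycles_per_audit must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.min_papers < 1:
            raise ValueError("min_papers must be >= 1")
        if self.statistic not in AUDIT_STATISTICS:
            raise ValueError(f"statistic must be one of {AUDIT_STATISTICS}, got {self.statistic!r}")
        if not 0.0 < self.cutoff_percentile <= 1.0:
            raise ValueError("cutoff_percentile must lie in (0, 1]")
        if self.review_error_pct < 0:
            raise ValueError("review_error_pct must be >= 0")
        if self.effort_boost_audited < 0 or self.effort_boost_network < 0:
            raise ValueError("effort boosts must be >= 0")

    @property
    def resolved_floor(self) -> float:
        if self.cutoff_floor is not None:
            return self.cutoff_floor
        if self.statistic in ("false_positive_proportion", "alpha"):
            return DEFAULT_FP_CUTOFF_FLOOR
        return 0.0


@dataclass(frozen=True)
class AuditRecord:
    """Outcome of one scheduled audit (or of a skipped one)."""

    cycle: int
    lab_id: Optional[int]
    papers_at_audit: int
    statistic_true: float
    statistic_observed: float
    cutoff: float
    removed: bool
    cost: float
    skipped: bool = False


def is_audit_cycle(cycle: int, policy: AuditPolicy) -> bool:
    """True on cycles where an audit is scheduled: after the burn-in,
    every ``cycles_per_audit`` cycles (first audit at burn_in + j)."""
    if not policy.enabled or cycle <= policy.burn_in:
        return False
    return (cycle - policy.burn_in) % policy.cycles_per_audit == 0


def eligible_labs(state: WorldState, policy: AuditPolicy) -> list:
    """Ids of living labs that were never audited and have published at
    least ``min_papers`` papers.  May be empty."""
    return [
        lab.id
        for lab in state.labs
        if not lab.audited and lab.papers >= policy.min_papers
    ]


def apply_reviewer_noise(count: int, papers: int, error_pct: float, rng) -> int:
    """Perturb an observed count to emulate imperfect peer review.

    A Normal error with standard deviation ``error_pct/100 * count /
    1.96`` is added and rounded, so the count is within +/- error_pct
    with 95% probability.  The result is clamped to [0, papers].  A zero
    count (or zero error) is returned unchanged.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if error_pct == 0 or count == 0:
        return int(count)
    sd = (error_pct / 100.0) * count / 1.96
    observed = int(round(count + rng.normal(0.0, sd)))
    return int(min(max(observed, 0), papers))


def _true_statistic(lab: LabState, policy: AuditPolicy, params: WorldParams) -> float:
    """Un-noised audit statistic; 0 for labs with no papers yet (used
    only when building the population cut-off distribution)."""
    if policy.statistic == "alpha":
        return false_positive_prob(params.power, lab.effort)
    if lab.papers == 0:
        return 0.0
    count = lab.false_positives if policy.statistic == "false_positive_proportion" else lab.mistakes
    return count / lab.papers


def audit_statistic(lab: LabState, policy: AuditPolicy, params: WorldParams, rng=None) -> float:
    """The (possibly reviewer-noised) audit statistic of one lab.

    Raises if the lab has no papers: a proportion is undefined and the
    eligibility rule guarantees audited labs have at least one.
    """
    if policy.statistic == "alpha":
        return false_positive_prob(params.power, lab.effort)
    if lab.papers < 1:
        raise ValueError("audit statistic undefined for a lab with no papers")
    count = lab.false_positives if policy.statistic == "false_positive_proportion" else lab.mistakes
    if policy.review_error_pct > 0 and rng is not None:
        count = apply_reviewer_noise(count, lab.papers, policy.review_error_pct, rng)
    return min(max(count / lab.papers, 0.0), 1.0)


def compute_cutoff(values, percentile: float, floor: float = 0.0) -> float:
    """Empirical removal cut-off: the ``percentile``-th quantile of the
    population's statistics (inverted-CDF convention, the smallest value
    whose empirical CDF reaches the percentile), floored at ``floor``.
    A percentile of 1.0 disables removal entirely (returns +inf)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot compute a cut-off from an empty list")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    if percentile >= 1.0:
        return math.inf
    k = math.ceil(percentile * vals.size) - 1
    return max(float(np.partition(vals, k)[k]), floor)


def conduct_audit(state: WorldState, policy: AuditPolicy, params: WorldParams,
                  cost_model: Optional[CostModel], rng) -> AuditRecord:
    """Run one audit on the world, in place.

    One eligible lab is drawn uniformly.  Its observed statistic is
    compared against the cut-off computed from all labs' un-noised
    statistics; above the cut-off the lab is removed and replaced via
    the usual birth procedure (no personal boost for a removed lab),
    otherwise it is marked audited and gains ``el+`` effort.  Either
    way its living parent and children gain ``en+``.
    """
    if cost_model is None:
        cost_model = CostModel()
    elig = eligible_labs(state, policy)
    if not elig:
        state.total_skipped_audits += 1
        return AuditRecord(state.cycle, None, 0, math.nan, math.nan, math.nan,
                           removed=False, cost=0.0, skipped=True)

    lab = state.lab_by_id(elig[int(rng.random() * len(elig))])
    stats_all = [_true_statistic(l, policy, params) for l in state.labs]
    cutoff = compute_cutoff(stats_all, policy.cutoff_percentile, policy.resolved_floor)
    stat_true = _true_statistic(lab, policy, params)
    stat_obs = audit_statistic(lab, policy, params, rng)

    papers_at_audit = lab.papers
    cost = audit_cost(papers_at_audit, cost_model)
    state.total_audits += 1
    state.total_audit_cost += cost
    state.total_audited_papers += papers_at_audit
    state.audited_ever.add(lab.id)

    old_id = lab.id
    old_parent_id = lab.parent_id
    replacement_id = None
    removed = stat_obs > cutoff
    if removed:
        state.labs.remove(lab)
        state.total_removals += 1
        jdx = rng.choice(len(state.labs), size=params.birth_sample, replace=False)
        pays = [state.labs[j].payoff for j in jdx]
        parent = state.labs[int(jdx[_argmax_random_tie(pays, rng)])]
        child = make_child(parent, params, rng, birth_cycle=state.cycle, lab_id=state.next_id)
        state.next_id += 1
        state.labs.append(child)
        state.register_birth(child)
        replacement_id = child.id
    else:
        lab.audited = True
        if policy.effort_boost_audited > 0:
            lab.effort = min(max(lab.effort + policy.effort_boost_audited, 1.0), 100.0)

    if policy.effort_boost_network > 0:
        for other in state.labs:
            in_network = (other.parent_id == old_id) or (
                old_parent_id is not None and other.id == old_parent_id
            )
            if in_network and other.id != replacement_id:
                other.effort = min(max(other.effort + policy.effort_boost_network, 1.0), 100.0)

    return AuditRecord(state.cycle, old_id, papers_at_audit,
                       stat_true, stat_obs, cutoff, removed=removed, cost=cost)
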