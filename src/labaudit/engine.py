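"""Compiled batch engine for scenario-scale runs.

Scenario-scale runs (hundreds of thousands of research cycles times
tens or hundreds of replicates) are far too long for the object-level
reference implementation in :mod:`labaudit.dynamics`, so the full model
-- lab research, death-birth selection, and audits -- is restated here
as a single numba-compiled kernel that runs one replicate start to
finish.  The object-level modules remain the readable reference; tests
pin the two implementations to the same closed-form limits and forced
paths.

Randomness contract
-------------------
Each replicate is simulated by one kernel call seeded from its own seed
(derived from the scenario master seed), so a replicate's trajectory
depends only on its own seed: row ``r`` of a batch is bit-identical to
a single-replicate run of replicate ``r``, regardless of batch size or
execution order.

Per cycle, each lab's research outcome is decided by a single uniform
``u`` compared against cached cumulative thresholds of the joint
outcome distribution (publish / pay-off / false positive / mistake),
which is distributionally identical to the staged draws of the
reference implementation.  Samples of ``d`` labs without replacement
use rejection sampling; ties (oldest lab, richest lab) are broken
uniformly at random.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from numba import njit

from .audit import AuditPolicy
from .dynamics import WorldParams
from .economics import CostModel

__all__ = ["BatchResult", "simulate_batch"]

_STAT_CODES = {"false_positive_proportion": 0, "alpha": 1, "mistake_proportion": 2}
_NO_REMOVAL = 1.0e30  # cut-off sentinel when the percentile is 1.0


@dataclass
class BatchResult:
    """Recorded trajectories for a batch of replicates.

    All record arrays have shape ``(n_records, n_replicates)``;
    cumulative fields cover everything produced since cycle 1,
    including by labs that were later removed.
    """

    record_cycles: np.ndarray
    mean_effort: np.ndarray
    mean_alpha: np.ndarray
    cum_papers: np.ndarray
    cum_false_positives: np.ndarray
    cum_mistakes: np.ndarray
    cum_audits: np.ndarray
    cum_skipped_audits: np.ndarray
    cum_removals: np.ndarray
    cum_audit_cost: np.ndarray
    cum_audited_papers: np.ndarray
    audit_log: Optional[list] = None

    @property
    def n_replicates(self) -> int:
        return self.mean_alpha.shape[1]

    @property
    def final_papers(self) -> np.ndarray:
        return self.cum_papers[-1]

    @property
    def final_false_positives(self) -> np.ndarray:
        return self.cum_false_positives[-1]

    @property
    def final_mistakes(self) -> np.ndarray:
        return self.cum_mistakes[-1]

    @property
    def final_mean_alpha(self) -> np.ndarray:
        return self.mean_alpha[-1]


@njit(cache=False)
def _thresholds(e, eta, q, W, mp, T1, T2, T3, T4, T5, i):
    """Cache the outcome thresholds for lab i at effort e.

    Segments of the per-cycle uniform u: [0, T1) true positive,
    [T1, T2) true negative, [T2, T3) false positive with mistake,
    [T3, T4) false positive without mistake, [T4, T5) false negative,
    [T5, 1) no new hypothesis tackled.
    """
    tackle = 1.0 - eta * math.log10(e)
    alpha = W / (1.0 + (1.0 - W) * e)
    t2 = tackle * q
    fp_w = tackle * (1.0 - q) * alpha
    T1[i] = t2 * W
    T2[i] = t2
    T3[i] = t2 + fp_w * mp
    T4[i] = t2 + fp_w
    T5[i] = tackle


@njit(cache=False)
def _sample_distinct(n, k, exclude, out):
    """k distinct indices from range(n), excluding ``exclude`` (pass -1
    for none), by rejection; uniform over subsets."""
    got = 0
    while got < k:
        cand = int(np.random.random() * n)
        if cand == exclude:
            continue
        dup = False
        for j in range(got):
            if out[j] == cand:
                dup = True
                break
        if not dup:
            out[got] = cand
            got += 1


@njit(cache=False)
def _pick_max(values, sample, k):
    """Index (into the population) of the max of ``values`` over
    ``sample[:k]``; ties broken uniformly."""
    best = values[sample[0]]
    for j in range(1, k):
        v = values[sample[j]]
        if v > best:
            best = v
    ties = 0
    for j in range(k):
        if values[sample[j]] == best:
            ties += 1
    if ties == 1:
        for j in range(k):
            if values[sample[j]] == best:
                return sample[j]
    pick = int(np.random.random() * ties)
    seen = 0
    for j in range(k):
        if values[sample[j]] == best:
            if seen == pick:
                return sample[j]
            seen += 1
    return sample[k - 1]  # unreachable


@njit(cache=False)
def _spawn_child(slot, parent, t, mut_p, mut_sd,
                 effort, birth, papers, fps, mists, positives, audited,
                 uid, parent_uid, next_uid,
                 eta, q, W, mp, T1, T2, T3, T4, T5):
    """Replace the lab at ``slot`` with a newborn child of ``parent``."""
    e = effort[parent]
    if np.random.random() < mut_p:
        e = e + np.random.normal(0.0, mut_sd)
        if e < 1.0:
            e = 1.0
        elif e > 100.0:
            e = 100.0
    effort[slot] = e
    birth[slot] = t
    papers[slot] = 0
    fps[slot] = 0
    mists[slot] = 0
    positives[slot] = 0
    audited[slot] = False
    parent_uid[slot] = uid[parent]
    uid[slot] = next_uid
    _thresholds(e, eta, q, W, mp, T1, T2, T3, T4, T5, slot)
    return next_uid + 1


@njit(cache=False)
def _run_replicate(seed, total_cycles, record_every,
                   L, eta, q, W, e0, mut_p, mut_sd, mp, ds, bs,
                   audits_on, burn_in, j, min_papers, stat_code,
                   cutoff_pct, floor, err_pct, el, en,
                   cost_mode, cost_per_auditor, papers_per_auditor,
                   rec_effort, rec_alpha, rec_papers, rec_fps, rec_mists,
                   rec_audits, rec_skipped, rec_removals, rec_cost,
                   rec_audited_papers,
                   collect, log_cycle, log_uid, log_papers, log_stat_true,
                   log_stat_obs, log_cutoff, log_removed, log_cost):
    """One replicate, start to finish.  Fills the rec_* arrays
    (one entry per record) and returns the number of logged audits."""
    np.random.seed(seed)

    effort = np.full(L, e0)
    birth = np.zeros(L, dtype=np.int64)
    papers = np.zeros(L, dtype=np.int64)
    fps = np.zeros(L, dtype=np.int64)
    mists = np.zeros(L, dtype=np.int64)
    positives = np.zeros(L, dtype=np.int64)
    audited = np.zeros(L, dtype=np.bool_)
    uid = np.arange(L).astype(np.int64)
    parent_uid = np.full(L, -1, dtype=np.int64)
    next_uid = L

    T1 = np.empty(L); T2 = np.empty(L); T3 = np.empty(L)
    T4 = np.empty(L); T5 = np.empty(L)
    for i in range(L):
        _thresholds(effort[i], eta, q, W, mp, T1, T2, T3, T4, T5, i)

    rem_papers = 0
    rem_fps = 0
    rem_mists = 0
    n_audits = 0
    n_skipped = 0
    n_removals = 0
    cost_sum = 0.0
    audited_papers = 0
    n_logged = 0

    samp = np.empty(ds if ds > bs else bs, dtype=np.int64)
    ages = np.empty(L, dtype=np.int64)
    stats = np.empty(L)
    cut_k = int(math.ceil(cutoff_pct * L)) - 1

    for t in range(1, total_cycles + 1):
        # --- all labs act --------------------------------------------
        for i in range(L):
            u = np.random.random()
            if u < T5[i]:
                papers[i] += 1
                if u < T1[i]:
                    positives[i] += 1            # true positive
                elif u >= T2[i]:
                    if u < T4[i]:                # false positive
                        positives[i] += 1
                        fps[i] += 1
                        if u < T3[i]:
                            mists[i] += 1
        # --- death: oldest of a random sample of ds ------------------
        _sample_distinct(L, ds, -1, samp)
        for i in range(L):
            ages[i] = t - birth[i]
        dead = _pick_max(ages, samp, ds)
        rem_papers += papers[dead]
        rem_fps += fps[dead]
        rem_mists += mists[dead]
        # --- birth: richest of a random sample of bs survivors -------
        _sample_distinct(L, bs, dead, samp)
        parent = _pick_max(positives, samp, bs)
        next_uid = _spawn_child(dead, parent, t, mut_p, mut_sd,
                                effort, birth, papers, fps, mists, positives,
                                audited, uid, parent_uid, next_uid,
                                eta, q, W, mp, T1, T2, T3, T4, T5)
        # --- audit ---------------------------------------------------
        if audits_on and t > burn_in and (t - burn_in) % j == 0:
            u_sel = np.random.random()
            n_elig = 0
            for i in range(L):
                if papers[i] >= min_papers and not audited[i]:
                    n_elig += 1
            if n_elig == 0:
                n_skipped += 1
            else:
                pick = int(u_sel * n_elig)
                a = -1
                seen = 0
                for i in range(L):
                    if papers[i] >= min_papers and not audited[i]:
                        if seen == pick:
                            a = i
                            break
                        seen += 1
                # un-noised statistics of all labs
                for i in range(L):
                    if stat_code == 1:
                        stats[i] = W / (1.0 + (1.0 - W) * effort[i])
                    elif papers[i] == 0:
                        stats[i] = 0.0
                    elif stat_code == 0:
                        stats[i] = fps[i] / papers[i]
                    else:
                        stats[i] = mists[i] / papers[i]
                if cutoff_pct >= 1.0:
                    cutoff = _NO_REMOVAL
                else:
                    cutoff = np.sort(stats)[cut_k]
                    if cutoff < floor:
                        cutoff = floor
                stat_true = stats[a]
                stat_obs = stat_true
                if err_pct > 0.0 and stat_code != 1:
                    count = fps[a] if stat_code == 0 else mists[a]
                    if count > 0:
                        sd = (err_pct / 100.0) * count / 1.96
                        obs = int(math.floor(count + np.random.normal(0.0, sd) + 0.5))
                        if obs < 0:
                            obs = 0
                        elif obs > papers[a]:
                            obs = papers[a]
                        stat_obs = obs / papers[a]
                papers_at = papers[a]
                if cost_mode == 0:
                    cost = papers_at * cost_per_auditor
                else:
                    cost = math.ceil(papers_at / papers_per_auditor) * cost_per_auditor
                n_audits += 1
                cost_sum += cost
                audited_papers += papers_at
                old_uid = uid[a]
                old_parent = parent_uid[a]
                replacement_uid = -1
                removed = stat_obs > cutoff
                if removed:
                    rem_papers += papers[a]
                    rem_fps += fps[a]
                    rem_mists += mists[a]
                    n_removals += 1
                    _sample_distinct(L, bs, a, samp)
                    parent = _pick_max(positives, samp, bs)
                    replacement_uid = next_uid
                    next_uid = _spawn_child(a, parent, t, mut_p, mut_sd,
                                            effort, birth, papers, fps, mists,
                                            positives, audited, uid, parent_uid,
                                            next_uid,
                                            eta, q, W, mp, T1, T2, T3, T4, T5)
                else:
                    audited[a] = True
                    if el > 0.0:
                        e = effort[a] + el
                        if e > 100.0:
                            e = 100.0
                        effort[a] = e
                        _thresholds(e, eta, q, W, mp, T1, T2, T3, T4, T5, a)
                if en > 0.0:
                    # the audited lab's living parent and children; the fresh
                    # child replacing a removed audited lab is not included
                    for i in range(L):
                        in_net = parent_uid[i] == old_uid or \
                            (old_parent >= 0 and uid[i] == old_parent)
                        if in_net and uid[i] != replacement_uid and i != a:
                            e = effort[i] + en
                            if e > 100.0:
                                e = 100.0
                            effort[i] = e
                            _thresholds(e, eta, q, W, mp, T1, T2, T3, T4, T5, i)
                if collect and n_logged < log_cycle.shape[0]:
                    log_cycle[n_logged] = t
                    log_uid[n_logged] = old_uid
                    log_papers[n_logged] = papers_at
                    log_stat_true[n_logged] = stat_true
                    log_stat_obs[n_logged] = stat_obs
                    log_cutoff[n_logged] = cutoff
                    log_removed[n_logged] = removed
                    log_cost[n_logged] = cost
                    n_logged += 1
        # --- record --------------------------------------------------
        if t % record_every == 0:
            k = t // record_every - 1
            se = 0.0
            sa = 0.0
            sp = 0
            sf = 0
            sm = 0
            for i in range(L):
                se += effort[i]
                sa += W / (1.0 + (1.0 - W) * effort[i])
                sp += papers[i]
                sf += fps[i]
                sm += mists[i]
            rec_effort[k] = se / L
            rec_alpha[k] = sa / L
            rec_papers[k] = rem_papers + sp
            rec_fps[k] = rem_fps + sf
            rec_mists[k] = rem_mists + sm
            rec_audits[k] = n_audits
            rec_skipped[k] = n_skipped
            rec_removals[k] = n_removals
            rec_cost[k] = cost_sum
            rec_audited_papers[k] = audited_papers
    return n_logged


def simulate_batch(world: WorldParams, policy: Optional[AuditPolicy],
                   costs: Optional[CostModel], *, total_cycles: int,
                   record_every: int, replicate_seeds: List[np.random.SeedSequence],
                   collect_audits: bool = False,
                   progress=None) -> BatchResult:
    """Simulate ``len(replicate_seeds)`` independent replicates.

    ``policy=None`` (or a disabled policy) runs the audit-free world.
    ``progress``, if given, is called as ``progress(done, total)``
    after each completed replicate.  With ``collect_audits=True`` the
    result carries a per-audit log (replicate, cycle, lab uid, papers,
    statistics, cut-off, removal, cost).
    """
    if total_cycles < 1 or total_cycles % record_every != 0:
        raise ValueError("total_cycles must be a positive multiple of record_every")
    if costs is None:
        costs = CostModel()
    if policy is None:
        policy = AuditPolicy(enabled=False)
    audits_on = policy.enabled

    R = len(replicate_seeds)
    n_records = total_cycles // record_every
    rec = {
        name: np.empty((n_records, R), dtype=dt)
        for name, dt in [
            ("mean_effort", float), ("mean_alpha", float),
            ("cum_papers", np.int64), ("cum_false_positives", np.int64),
            ("cum_mistakes", np.int64), ("cum_audits", np.int64),
            ("cum_skipped_audits", np.int64), ("cum_removals", np.int64),
            ("cum_audit_cost", float), ("cum_audited_papers", np.int64),
        ]
    }
    max_audits = (
        max(0, (total_cycles - policy.burn_in)) // policy.cycles_per_audit + 1
        if audits_on else 1
    )
    log_size = max_audits if collect_audits else 1
    audit_log = [] if collect_audits else None

    for r, ss in enumerate(replicate_seeds):
        seed = int(ss.generate_state(1, dtype=np.uint32)[0])
        log = {
            "cycle": np.zeros(log_size, dtype=np.int64),
            "uid": np.zeros(log_size, dtype=np.int64),
            "papers": np.zeros(log_size, dtype=np.int64),
            "stat_true": np.zeros(log_size),
            "stat_obs": np.zeros(log_size),
            "cutoff": np.zeros(log_size),
            "removed": np.zeros(log_size, dtype=np.bool_),
            "cost": np.zeros(log_size),
        }
        n_logged = _run_replicate(
            seed, total_cycles, record_every,
            world.population_size, world.eta, world.truth_prior, world.power,
            float(world.initial_effort), world.mutation_prob, world.mutation_sd,
            world.mistake_prob, world.death_sample, world.birth_sample,
            audits_on, policy.burn_in, policy.cycles_per_audit,
            policy.min_papers, _STAT_CODES[policy.statistic],
            policy.cutoff_percentile, policy.resolved_floor,
            policy.review_error_pct, policy.effort_boost_audited,
            policy.effort_boost_network,
            0 if costs.cost_mode == "results_consistent" else 1,
            costs.cost_per_auditor, costs.papers_per_auditor,
            rec["mean_effort"][:, r], rec["mean_alpha"][:, r],
            rec["cum_papers"][:, r], rec["cum_false_positives"][:, r],
            rec["cum_mistakes"][:, r], rec["cum_audits"][:, r],
            rec["cum_skipped_audits"][:, r], rec["cum_removals"][:, r],
            rec["cum_audit_cost"][:, r], rec["cum_audited_papers"][:, r],
            collect_audits, log["cycle"], log["uid"], log["papers"],
            log["stat_true"], log["stat_obs"], log["cutoff"], log["removed"],
            log["cost"],
        )
        if collect_audits:
            for m in range(n_logged):
                audit_log.append(dict(
                    replicate=r, cycle=int(log["cycle"][m]),
                    lab_uid=int(log["uid"][m]), papers=int(log["papers"][m]),
                    statistic_true=float(log["stat_true"][m]),
                    statistic_observed=float(log["stat_obs"][m]),
                    cutoff=float(log["cutoff"][m]),
                    removed=bool(log["removed"][m]), cost=float(log["cost"][m]),
                ))
        if progress is not None:
            progress(r + 1, R)

    return BatchResult(
        record_cycles=np.arange(1, n_records + 1) * record_every,
        audit_log=audit_log,
        **rec,
    )
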