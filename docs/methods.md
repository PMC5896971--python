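# Model and methods

`labaudit` simulates a research world in which competing laboratories
are selected on publication output, and asks whether randomly auditing
a small fraction of the literature can prevent the selection-driven
collapse of research quality.

## The research world

The world holds a fixed population of `N = 100` labs.  Each lab `i`
carries a single heritable trait, its *effort* `e_i ∈ [1, 100]`, which
is the time and care invested per hypothesis.  Statistical power is
fixed at `W = 0.8` for all labs: the interesting dynamics are in
effort, not methodology.

One *research cycle* comprises, in order:

1. **Research.**  Every lab takes on a new hypothesis with probability
   `1 − η log₁₀ e_i` (with `η = 0.2`: 0.6 at `e = 100`, 1.0 at
   `e = 1`).  The hypothesis is true with prior probability 0.1.  A
   true hypothesis tests positive with probability `W`; a false one
   with probability

       α_i = W / (1 + (1 − W) e_i),

   the lab's false-positive probability, which runs from 0.05 at
   `e = 75` down the effort scale to 2/3 at `e = 1`.  Every tested
   hypothesis is written up and published as a paper; positive results
   (true or false) earn a pay-off of 1, and a false-positive paper
   carries a detectable *mistake* with probability 0.25.  Negative
   results are published but earn nothing.
2. **Death.**  Ten labs are drawn at random; the oldest of them (ties
   uniform) retires.  Mean lab lifetime is therefore exactly 100
   cycles.
3. **Birth.**  Ten of the 99 survivors are drawn at random; the one
   with the highest cumulative pay-off (ties uniform) founds a child
   lab that inherits its effort — mutated, with probability 0.01, by a
   `N(0, 1)` offset and clamped to `[1, 100]` — and starts with an
   empty record.
4. **Audit** (if scheduled; see below).

Because low effort raises both the tackling rate and `α`, pay-off
selection favours low effort.  Left alone, mutation plus selection
drives mean effort to 1 and mean `α` to its maximum of 0.67 — the
*competitive spiral*.  A replicate is classified as having spiralled
when the mean `α` of its final record is at least 0.6; end states are
strongly bimodal (near 0.05 or near 0.67), so the classification is
insensitive to the exact threshold, which is configurable.

### Publication model

Every tackled hypothesis becomes a published paper, while the pay-off
that drives selection accrues only to positive results.  The paper
count is what audit eligibility, audit statistics and all per-paper
rates are measured against.  This is the reading consistent with the
model's own arithmetic: labs live ~100 cycles, so an eligibility bar
of 50 papers is only reachable when papers accrue at the tackling rate
(~0.625/cycle at `e = 75`), and the audit-burden figures (≈1.94% of
papers audited at `j = 50`) follow directly.

## Audits

After a 100-cycle burn-in an audit is scheduled every `j` cycles
(first at `100 + j`).  One lab is drawn uniformly from those that were
never audited before and have at least `n` papers (default 50); if no
lab qualifies the audit is skipped.  The auditors compute the lab's
cumulative *audit statistic*:

* `false_positive_proportion` (default): realized false positives /
  papers, optionally perturbed by reviewer noise (below);
* `alpha`: the lab's current `α_i` (an idealised auditor who can see
  effort directly);
* `mistake_proportion`: papers with detected mistakes / papers, for
  the variant where auditors can only count mistakes.

The removal cut-off `c` is the empirical `F(c) = 0.67` quantile
(inverted-CDF convention) of the un-noised statistics of all 100
current labs, floored at 0.05 for the false-positive statistics so
labs are never removed for a rate an ideal lab could show (no floor
for mistake proportions, where the ideal rate is 0).  A lab whose
observed statistic exceeds the cut-off is removed and replaced through
the ordinary birth step; with exchangeable statistics this removes the
audited lab in about one audit in three.  A surviving audited lab
raises its effort by `el⁺` (default 5), and the lab's living parent
and children raise theirs by `en⁺` (default 5) — the *network effect*,
the main channel through which audits help.  A cut-off percentile of
1.0 disables removal entirely.

Reviewer noise (sensitivity analysis) perturbs the observed
false-positive count by a rounded `N(0, (p/100)·FP/1.96)` draw
(`p = 20` by default when enabled), clamped to `[0, papers]`, so the
count is within ±p% with 95% probability.  The cut-off distribution
itself stays un-noised.

## Costs

Auditors earn 105,000 USD/year and work one month per engagement.  The
default `results_consistent` costing charges one auditor-month per
audited paper (8,750 USD), which makes cost-per-paper equal 8,750 ×
(fraction of papers audited) and reproduces the published cost figures
(≈169 USD per paper at 1.94% audited; 15.9M USD/year for 94,000
NIH-funded papers).  The alternative `text_literal` costing charges
one auditor-month per ten audited papers and is ten times cheaper; the
two readings are mutually inconsistent and both are provided.

## Scenarios and summaries

A scenario runs `n_replicates` independent replicates of
`total_cycles` cycles (defaults 500 × 800,000), recording the world
every 8,000 cycles (100 records).  Summaries report the percent of
replicates avoiding the spiral and the across-replicate means with
non-parametric 95% CIs (2.5th/97.5th empirical percentiles) of: percent
of papers audited, audit cost per published paper, and false positives
and mistakes per 100 papers — all cumulative over the whole run,
including the output of labs that were later removed.
`sensitivity_scenarios()` builds the 16-scenario sensitivity sweep (audit
cadence, cut-offs, boost asymmetries, eligibility bar, reviewer noise,
low starting effort, mistake-based audits, and the audit-free world).

## Numerical and design notes

* **Two implementations.**  `dynamics`/`audit` are the object-level
  reference implementation; `engine` restates the identical model as a
  numba kernel for scenario-scale runs.  Per cycle the kernel decides
  each lab's outcome from a single uniform against cached cumulative
  thresholds of the joint outcome distribution, which is
  distributionally identical to the reference's staged draws.  Tests
  pin both to the same closed-form limits, forced paths and invariants.
* **Randomness.**  Each replicate is seeded from its own
  `SeedSequence` child of the scenario master seed, so batches are
  reproducible bit-for-bit, row by row, independent of batch size or
  execution order.
* **Sampling without replacement** (death/birth samples of 10) uses
  rejection sampling; ties in age or pay-off are broken uniformly.
* **Quantiles.**  The removal cut-off and the summary CIs use the
  inverted-CDF (type-1) empirical quantile, matching a sort-and-index
  oracle exactly.
* **Clamping.**  Effort is clamped to `[1, 100]` after mutation and
  after audit boosts.  A removed audited lab gets no personal boost
  (there is no lab left to boost) but its network boost still applies;
  the replacement child is not part of the removed lab's network.
* **Degenerate inputs.**  Audit statistics are undefined for zero-paper
  labs (eligibility prevents it; the population cut-off distribution
  scores such labs 0).  Zero-paper worlds raise on per-paper rates.
* **Problem sizes.**  The acceptance script and the end-to-end tests
  use 30 replicates per scenario at the full 800,000 cycles, the
  package's reduced study size for routine verification; binomial
  error at 30 replicates (±8–16 percentage points on spiral rates) is
  the limiting precision there.

## What the simulation does and does not show

The generator *is* the study design: all conclusions are about this
stylised world — one trait under selection, a single fixed power,
hypothesis priors and mistake rates set by assumption, no journals,
no replication attempts, no strategic response to audit design.  In
particular mistakes occur only in false-positive papers, audits never
err about the record itself (except through the optional reviewer
noise), and a lab's "network" is only its direct parent and children.
Passing tests show the model's internal logic and published summaries
are reproduced, not that audits would behave this way in the real
research system.
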