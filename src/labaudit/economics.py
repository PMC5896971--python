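"""Audit cost accounting and national scale-up arithmetic.

Auditors are salaried senior researchers (annual salary 105,000 USD,
the 2016 inflation-adjusted mean of professor and associate-professor
salaries) employed for one month per audit task.  Two costings are
provided:

* ``results_consistent`` (default): one auditor-month per audited paper
  (105,000 / 12 = 8,750 USD per paper).  This is the costing implied by
  the headline figures -- 169 USD per published paper when 1.94% of
  papers are audited, and 15.9M USD per year to audit 1,824 NIH papers.
* ``text_literal``: one auditor (one month) per 10 audited papers,
  i.e. roughly 875 USD per audited paper -- ten times cheaper.

The two disagree by a factor of ten; the default keeps the published
cost figures reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostModel",
    "COST_MODES",
    "audit_cost",
    "percent_papers_audited",
    "cost_per_paper",
    "national_scaleup",
]

COST_MODES = ("results_consistent", "text_literal")


@dataclass(frozen=True)
class CostModel:
    annual_salary: float = 105_000.0
    months_per_auditor: float = 1.0
    papers_per_auditor: int = 10
    cost_mode: str = "results_consistent"

    def __post_init__(self) -> None:
        if self.annual_salary <= 0 or self.months_per_auditor <= 0:
            raise ValueError("annual_salary and months_per_auditor must be positive")
        if self.papers_per_auditor < 1:
            raise ValueError("papers_per_auditor must be >= 1")
        if self.cost_mode not in COST_MODES:
            raise ValueError(f"cost_mode must be one of {COST_MODES}, got {self.cost_mode!r}")

    @property
    def cost_per_auditor(self) -> float:
        """Salary cost of one auditor for one audit engagement."""
        return self.annual_salary / 12.0 * self.months_per_auditor


def audit_cost(papers_at_audit: int, model: CostModel) -> float:
    """Cost of auditing one lab with ``papers_at_audit`` papers."""
    if papers_at_audit < 1:
        raise ValueError("an audited lab must have at least one paper")
    if model.cost_mode == "results_consistent":
        return papers_at_audit * model.cost_per_auditor
    n_auditors = math.ceil(papers_at_audit / model.papers_per_auditor)
    return n_auditors * model.cost_per_auditor


def percent_papers_audited(audited_papers: int, total_papers: int) -> float:
    """Percent of all published papers that were covered by an audit."""
    if total_papers <= 0:
        raise ValueError("total_papers must be positive")
    return 100.0 * audited_papers / total_papers


def cost_per_paper(total_audit_cost: float, total_papers: int) -> float:
    """Audit spend spread over every published paper (audited or not)."""
    if total_papers <= 0:
        raise ValueError("total_papers must be positive")
    return total_audit_cost / total_papers


def national_scaleup(annual_papers: int, percent_audited: float,
                     cost_per_paper_usd: float) -> tuple[int, float]:
    """Scale the simulated audit burden to a national research system.

    Returns ``(papers audited per year, annual cost in USD)``; e.g.
    94,000 NIH-funded papers at 1.94% audited and 169 USD per paper
    gives 1,824 audited papers at 15.9M USD per year.
    """
    if annual_papers < 0 or percent_audited < 0 or cost_per_paper_usd < 0:
        raise ValueError("inputs must be non-negative")
    audited = int(round(annual_papers * percent_audited / 100.0))
    return audited, annual_papers * cost_per_paper_usd
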