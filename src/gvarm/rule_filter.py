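"""Five-constraint post-filter for mined association rules.

Candidate rules from the miner are screened by five constraints and the
survivors ranked by lift:

* **AC** — temporal antecedent/consequent ordering: either all
  antecedent items are awake metrics of day N-1 and the consequent a
  sleep metric of day N, or all antecedent items are sleep metrics of
  day N and the consequent an awake metric of day N.
* **SC** — clinical significance: every item label must be extreme
  ("severe low", "low", "L1", "high", "severe high" or "L3"); rules
  touching "normal" or "L2" are discarded.
* **SS** — statistical significance: one-sided Fisher exact test of the
  rule's 2x2 contingency table, kept when p < 0.05.
* **MI** — normalized mutual information of the two binary indicators
  (mutual information over the minimum marginal entropy), kept when
  MI > 0.3.
* **kappa** — Cohen's kappa of the indicators (observed agreement
  corrected by chance agreement), kept when kappa > 0.3.

Fisher's p is compared strictly below alpha; MI and kappa strictly
above their thresholds, so boundary values fail. Probabilities are
maximum-likelihood counts/n with no smoothing. Redundant rules (whose
antecedent extends another survivor's without improving any measure)
are *not* removed by default; an optional pruning pass is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GvarmError
from .qarm import CandidateRule, TransactionDataset, rule_item_ids

logger = logging.getLogger(__name__)

LOW_LABELS = frozenset({"severe low", "low", "L1"})
HIGH_LABELS = frozenset({"severe high", "high", "L3"})
EXTREME_LABELS = LOW_LABELS | HIGH_LABELS


@dataclass(frozen=True)
class RuleContingency:
    """2x2 co-occurrence counts of a rule's antecedent and consequent."""

    n11: int  # antecedent and consequent
    n10: int  # antecedent only
    n01: int  # consequent only
    n00: int  # neither
    n: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise GvarmError("contingency counts must be non-negative")
        if self.n11 + self.n10 + self.n01 + self.n00 != self.n:
            raise GvarmError("contingency counts must sum to n")


def contingency(rule: CandidateRule, dataset: TransactionDataset
                ) -> RuleContingency:
    """Exact 2x2 counts of a rule over a transaction dataset."""
    ant_ids, csq_id = rule_item_ids(rule, dataset)
    ant = dataset.matrix[:, ant_ids].all(axis=1)
    csq = dataset.matrix[:, csq_id]
    n11 = int((ant & csq).sum())
    n10 = int((ant & ~csq).sum())
    n01 = int((~ant & csq).sum())
    n = dataset.n_transactions
    return RuleContingency(n11=n11, n10=n10, n01=n01,
                           n00=n - n11 - n10 - n01, n=n)


def ac_constraint(rule: CandidateRule) -> bool:
    """Temporal ordering: awake(N-1) => sleep(N), or sleep(N) => awake(N)."""
    ant_groups = {(i.role, i.lag) for i in rule.antecedent}
    csq_group = (rule.consequent.role, rule.consequent.lag)
    if ant_groups == {("awake", 1)} and csq_group == ("sleep", 0):
        return True
    if ant_groups == {("sleep", 0)} and csq_group == ("awake", 0):
        return True
    return False


def sc_constraint(rule: CandidateRule) -> bool:
    """Clinical extremeness: every item label low-set or high-set."""
    labels = {i.label for i in rule.antecedent} | {rule.consequent.label}
    return labels <= EXTREME_LABELS


def fisher_one_sided(ct: RuleContingency) -> float:
    """One-sided (greater) Fisher exact p: probability of >= n11
    co-occurrences under independence given the margins."""
    _, p = sps.fisher_exact([[ct.n11, ct.n10], [ct.n01, ct.n00]],
                            alternative="greater")
    return float(p)


def _entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * np.log(p) + (1 - p) * np.log(1 - p))


def normalized_mi(ct: RuleContingency) -> float:
    """Mutual information of the two indicators over the minimum of
    their marginal entropies; in [0, 1], with 0*log0 terms zero.

    Degenerate margins (an indicator always or never present) carry no
    information: the value is 0 by convention, with a warning.
    """
    n = ct.n
    p_ant = (ct.n11 + ct.n10) / n
    p_csq = (ct.n11 + ct.n01) / n
    if p_ant in (0.0, 1.0) or p_csq in (0.0, 1.0):
        logger.warning("degenerate margin: normalized MI set to 0")
        return 0.0
    mi = 0.0
    for joint, pi, pj in (
            (ct.n11 / n, p_ant, p_csq),
            (ct.n10 / n, p_ant, 1 - p_csq),
            (ct.n01 / n, 1 - p_ant, p_csq),
            (ct.n00 / n, 1 - p_ant, 1 - p_csq)):
        if joint > 0:
            mi += joint * np.log(joint / (pi * pj))
    norm = min(_entropy(p_ant), _entropy(p_csq))
    return float(min(max(mi / norm, 0.0), 1.0))


def cohen_kappa(ct: RuleContingency) -> float:
    """Cohen's kappa of antecedent/consequent presence: observed
    agreement corrected by expected agreement; in [-1, 1].

    Returns ``nan`` (and the rule fails the constraint) when the
    chance-agreement denominator is zero.
    """
    n = ct.n
    p_ant = (ct.n11 + ct.n10) / n
    p_csq = (ct.n11 + ct.n01) / n
    observed = (ct.n11 + ct.n00) / n
    expected = p_ant * p_csq + (1 - p_ant) * (1 - p_csq)
    denom = 1.0 - expected
    if denom == 0.0:
        logger.warning("kappa undefined (zero denominator)")
        return float("nan")
    return float((observed - expected) / denom)


@dataclass
class ScoredRule:
    """A candidate rule with its five post-filter scores and verdicts."""

    rule: CandidateRule
    fisher_p: float
    mi: float
    kappa: float
    passes: dict = field(default_factory=dict)
    survives: bool = False
    rank: int | None = None

    def as_row(self) -> dict:
        return {
            "rank": self.rank,
            "antecedent": "; ".join(str(i) for i in self.rule.antecedent),
            "consequent": str(self.rule.consequent),
            "kappa": self.kappa, "mi": self.mi,
            "supp": self.rule.support, "conf": self.rule.confidence,
            "lift": self.rule.lift, "fisher_p": self.fisher_p,
            "survives": self.survives,
            **{f"pass_{k}": v for k, v in self.passes.items()},
        }


def score_rule(rule: CandidateRule, dataset: TransactionDataset,
               alpha: float = 0.05, mi_min: float = 0.3,
               kappa_min: float = 0.3) -> ScoredRule:
    ct = contingency(rule, dataset)
    p = fisher_one_sided(ct)
    mi = normalized_mi(ct)
    kappa = cohen_kappa(ct)
    passes = {
        "ac": ac_constraint(rule),
        "sc": sc_constraint(rule),
        "ss": p < alpha,
        "mi": mi > mi_min,
        "kappa": bool(not np.isnan(kappa) and kappa > kappa_min),
    }
    return ScoredRule(rule=rule, fisher_p=p, mi=mi, kappa=kappa,
                      passes=passes, survives=all(passes.values()))


def apply_postfilter(rules: list[CandidateRule], dataset: TransactionDataset,
                     alpha: float = 0.05, mi_min: float = 0.3,
                     kappa_min: float = 0.3, prune_redundant: bool = False
                     ) -> list[ScoredRule]:
    """Score all candidate rules and rank the survivors by lift.

    Every rule is returned with its five scores; survivors (all five
    constraints true) carry a 1-based ``rank`` in descending lift order
    (ties broken by confidence, support, then canonical item order).
    ``prune_redundant`` optionally removes survivors whose antecedent is
    a strict superset of another survivor's with the same consequent and
    no better scores (off by default).
    """
    scored = [score_rule(r, dataset, alpha, mi_min, kappa_min) for r in rules]
    survivors = [s for s in scored if s.survives]
    if prune_redundant:
        keep = []
        for s in survivors:
            dominated = any(
                o is not s
                and o.rule.consequent == s.rule.consequent
                and set(o.rule.antecedent) < set(s.rule.antecedent)
                and o.rule.lift >= s.rule.lift
                and o.rule.confidence >= s.rule.confidence
                and o.mi >= s.mi and o.kappa >= s.kappa
                for o in survivors)
            if dominated:
                s.survives = False
                logger.info("pruned redundant rule %s", s.rule)
            else:
                keep.append(s)
        survivors = keep
    survivors.sort(key=lambda s: (-s.rule.lift, -s.rule.confidence,
                                  -s.rule.support, s.rule.antecedent,
                                  s.rule.consequent))
    for i, s in enumerate(survivors, start=1):
        s.rank = i
    scored.sort(key=lambda s: (s.rank is None, s.rank if s.rank is not None
                               else 0, s.rule.antecedent, s.rule.consequent))
    return scored


def scored_rules_frame(scored: list[ScoredRule]) -> pd.DataFrame:
    """Tabular view of scored rules (survivors first, by rank)."""
    if not scored:
        return pd.DataFrame(columns=[
            "rank", "antecedent", "consequent", "kappa", "mi", "supp",
            "conf", "lift", "fisher_p", "survives",
            "pass_ac", "pass_sc", "pass_ss", "pass_mi", "pass_kappa"])
    return pd.DataFrame([s.as_row() for s in scored])
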