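"""Five-constraint rule post-filter: contingency scores and screening."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from gvarm import (CandidateRule, RuleContingency, ac_constraint,
                   apply_postfilter, cohen_kappa, contingency,
                   dataset_from_itemsets, fisher_one_sided, normalized_mi,
                   sc_constraint)
from gvarm.qarm import Item


def make_rule(antecedent, consequent, **kw):
    defaults = dict(support=0.1, confidence=0.8, lift=2.5, n_rule=1,
                    n_antecedent=1, n_consequent=1, n_total=10)
    defaults.update(kw)
    return CandidateRule(antecedent=tuple(antecedent), consequent=consequent,
                         **defaults)


def random_tables(n_tables, seed, n_max=60):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_tables:
        n = int(rng.integers(8, n_max))
        cells = rng.multinomial(n, rng.dirichlet(np.ones(4)))
        ct = RuleContingency(*map(int, cells), n=n)
        out.append(ct)
    return out


def mi_oracle(ct):
    """Direct entropy-formula route, independent of the implementation."""
    n = ct.n
    joint = np.array([[ct.n11, ct.n10], [ct.n01, ct.n00]], float) / n
    pa = joint.sum(axis=1)   # antecedent present / absent
    pc = joint.sum(axis=0)
    if 0.0 in pa or 0.0 in pc:
        return 0.0
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log(joint[i, j] / (pa[i] * pc[j]))
    h = lambda p: -sum(q * math.log(q) for q in p if q > 0)
    return mi / min(h(pa), h(pc))


def kappa_oracle(ct):
    n = ct.n
    pa, pc = (ct.n11 + ct.n10) / n, (ct.n11 + ct.n01) / n
    po = (ct.n11 + ct.n00) / n
    pe = pa * pc + (1 - pa) * (1 - pc)
    return (po - pe) / (1 - pe) if pe != 1 else float("nan")


def fisher_oracle(ct):
    """Hypergeometric upper-tail route."""
    K = ct.n11 + ct.n01       # consequent margin
    draws = ct.n11 + ct.n10   # antecedent margin
    return float(hypergeom.sf(ct.n11 - 1, ct.n, K, draws))


class TestContingency:
    def test_hand_counted(self):
        ds = dataset_from_itemsets([{0, 1}, {0, 1, 2}, {0, 2}, {1}])
        rule = make_rule([ds.table.item(0)], ds.table.item(1))
        ct = contingency(rule, ds)
        assert (ct.n11, ct.n10, ct.n01, ct.n00) == (2, 1, 1, 0)

    def test_disjoint_items(self):
        ds = dataset_from_itemsets([{0}, {1}, {0}, {1}])
        ct = contingency(make_rule([ds.table.item(0)], ds.table.item(1)), ds)
        assert ct.n11 == 0 and ct.n == 4

    def test_counts_partition(self):
        ds = dataset_from_itemsets([{0, 1, 2}, {0}, {1, 2}, set(), {2}])
        ct = contingency(make_rule([ds.table.item(0), ds.table.item(1)],
                                   ds.table.item(2)), ds)
        assert ct.n11 + ct.n10 + ct.n01 + ct.n00 == 5


class TestAcConstraint:
    def test_sleep_to_same_day_awake_allowed(self):
        rule = make_rule([Item("min", "sleep", 0, "severe low"),
                          Item("mgn", "sleep", 0, "low")],
                         Item("lbgi", "awake", 0, "L3"))
        assert ac_constraint(rule)

    def test_previous_awake_to_sleep_allowed(self):
        rule = make_rule([Item("sd", "awake", 1, "L3")],
                         Item("cv", "sleep", 0, "L1"))
        assert ac_constraint(rule)

    def test_reversed_temporal_order_rejected(self):
        rule = make_rule([Item("lbgi", "awake", 0, "L3")],
                         Item("min", "sleep", 0, "severe low"))
        assert not ac_constraint(rule)

    def test_mixed_antecedent_groups_rejected(self):
        rule = make_rule([Item("sd", "awake", 1, "L3"),
                          Item("min", "sleep", 0, "low")],
                         Item("cv", "sleep", 0, "L1"))
        assert not ac_constraint(rule)


class TestScConstraint:
    def test_low_set_and_high_set_mixture_allowed(self):
        rule = make_rule([Item("min", "sleep", 0, "severe low"),
                          Item("mgn", "sleep", 0, "low")],
                         Item("lbgi", "awake", 0, "L3"))
        assert sc_constraint(rule)

    def test_high_antecedent_low_consequent_allowed(self):
        rule = make_rule([Item("sd", "awake", 1, "L3"),
                          Item("lbgi", "awake", 1, "L3")],
                         Item("mage", "sleep", 0, "L1"))
        assert sc_constraint(rule)

    @pytest.mark.parametrize("label", ["normal", "L2"])
    def test_middle_labels_rejected(self, label):
        rule = make_rule([Item("mean", "sleep", 0, label)],
                         Item("lbgi", "awake", 0, "L3"))
        assert not sc_constraint(rule)


class TestFisher:
    def test_all_concordant_table(self):
        p = fisher_one_sided(RuleContingency(4, 0, 0, 4, 8))
        assert p == pytest.approx(1 / 70)

    def test_independence_proportioned_table(self):
        # margins 4x4 over n=16 with n11 exactly at expectation 1
        p = fisher_one_sided(RuleContingency(1, 3, 3, 9, 16))
        assert p > 0.05

    @pytest.mark.parametrize("seed", [0, 1])
    def test_in_unit_interval_and_matches_oracle(self, seed):
        for ct in random_tables(100, seed):
            p = fisher_one_sided(ct)
            assert 0.0 < p <= 1.0
            assert p == pytest.approx(fisher_oracle(ct), abs=1e-10)


class TestNormalizedMi:
    def test_independent_indicators(self):
        assert normalized_mi(RuleContingency(4, 4, 4, 4, 16)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_perfect_co_occurrence(self):
        assert normalized_mi(RuleContingency(8, 0, 0, 8, 16)) \
            == pytest.approx(1.0)

    def test_degenerate_margin_is_zero(self):
        assert normalized_mi(RuleContingency(5, 0, 5, 0, 10)) == 0.0

    @pytest.mark.parametrize("seed", [2, 3])
    def test_matches_entropy_oracle(self, seed):
        for ct in random_tables(100, seed):
            got = normalized_mi(ct)
            assert 0.0 <= got <= 1.0
            assert got == pytest.approx(mi_oracle(ct), abs=1e-12)

    def test_symmetric_under_swap(self):
        for ct in random_tables(50, 5):
            swapped = RuleContingency(ct.n11, ct.n01, ct.n10, ct.n00, ct.n)
            assert normalized_mi(ct) == pytest.approx(normalized_mi(swapped),
                                                      abs=1e-12)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(RuleContingency(5, 0, 0, 5, 10)) == pytest.approx(1.0)

    def test_independence(self):
        assert cohen_kappa(RuleContingency(4, 4, 4, 4, 16)) \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [6, 7])
    def test_matches_direct_formula(self, seed):
        for ct in random_tables(100, seed):
            got = cohen_kappa(ct)
            want = kappa_oracle(ct)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12
                assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_under_swap(self):
        for ct in random_tables(50, 8):
            swapped = RuleContingency(ct.n11, ct.n01, ct.n10, ct.n00, ct.n)
            assert cohen_kappa(ct) == pytest.approx(cohen_kappa(swapped),
                                                    abs=1e-12)


class TestMonotonicityInCoOccurrence:
    def test_scores_increase_with_n11_at_fixed_margins(self):
        # margins: antecedent 10, consequent 12, n 40
        prev = None
        for n11 in range(0, 11):
            ct = RuleContingency(n11, 10 - n11, 12 - n11, 18 + n11, 40)
            scores = (normalized_mi(ct), cohen_kappa(ct),
                      -math.log(fisher_one_sided(ct)))
            if prev is not None and n11 >= 4:   # past the independence point
                assert scores[0] >= prev[0] - 1e-12
                assert scores[1] >= prev[1] - 1e-12
                assert scores[2] >= prev[2] - 1e-12
            prev = scores


class TestPostfilter:
    def make_dataset_and_rules(self):
        items = (Item("min", "sleep", 0, "severe low"),
                 Item("lbgi", "awake", 0, "L3"),
                 Item("mean", "sleep", 0, "normal"))
        # severe-low nights nearly always followed by high LBGI
        rows = [{0, 1}] * 8 + [{2}] * 20 + [{1}] * 2 + [set()] * 10
        ds = dataset_from_itemsets(rows, items=items)
        good = make_rule([items[0]], items[1], support=0.2, confidence=1.0,
                         lift=4.0, n_rule=8, n_antecedent=8, n_consequent=10,
                         n_total=40)
        bad_sc = make_rule([items[2]], items[1], support=0.0, confidence=0.0,
                           lift=0.0, n_rule=0, n_antecedent=20,
                           n_consequent=10, n_total=40)
        return ds, [good, bad_sc]

    def test_survivors_subset_and_ranked_by_lift(self):
        ds, rules = self.make_dataset_and_rules()
        scored = apply_postfilter(rules, ds)
        survivors = [s for s in scored if s.survives]
        assert len(survivors) == 1
        assert survivors[0].rank == 1
        assert survivors[0].rule is rules[0]
        assert all(s.rule in rules for s in scored)

    def test_idempotent(self):
        ds, rules = self.make_dataset_and_rules()
        first = [s.rule for s in apply_postfilter(rules, ds) if s.survives]
        second = [s.rule for s in apply_postfilter(first, ds) if s.survives]
        assert first == second

    def test_boundary_values_fail_strict_comparisons(self):
        # a contingency engineered to hit kappa slightly above/below 0.3
        ds, rules = self.make_dataset_and_rules()
        scored = apply_postfilter(rules, ds, kappa_min=1.1)
        assert not any(s.survives for s in scored)

    def test_redundant_pruning_flag(self):
        items = (Item("min", "sleep", 0, "severe low"),
                 Item("sd", "sleep", 0, "L1"),
                 Item("lbgi", "awake", 0, "L3"))
        rows = [{0, 1, 2}] * 8 + [set()] * 24 + [{2}] * 2
        ds = dataset_from_itemsets(rows, items=items)
        short = make_rule([items[0]], items[2], support=8 / 34,
                          confidence=1.0, lift=3.4, n_rule=8, n_antecedent=8,
                          n_consequent=10, n_total=34)
        long = make_rule([items[0], items[1]], items[2], support=8 / 34,
                         confidence=1.0, lift=3.4, n_rule=8, n_antecedent=8,
                         n_consequent=10, n_total=34)
        default = apply_postfilter([short, long], ds)
        assert sum(s.survives for s in default) == 2   # no pruning by default
        pruned = apply_postfilter([short, long], ds, prune_redundant=True)
        kept = [s for s in pruned if s.survives]
        assert len(kept) == 1 and kept[0].rule is short
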