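"""Discretization, transaction building and Apriori rule mining."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from gvarm import (ConfigError, apriori, build_attribute_table,
                   dataset_from_itemsets, fit_discretization, generate_rules,
                   transform)
from gvarm.qarm import Item, attribute_column, parse_attribute_column


def brute_force_itemsets(transactions, min_supp, max_size):
    """Exhaustive per-transaction enumeration oracle."""
    n = len(transactions)
    counter = Counter()
    for t in transactions:
        items = sorted(t)
        for size in range(1, max_size + 1):
            for combo in itertools.combinations(items, size):
                counter[frozenset(combo)] += 1
    return {s: c for s, c in counter.items()
            if c / n >= min_supp - 1e-12}


def brute_force_rules(transactions, min_supp, min_conf, min_lift):
    """Enumerate every (antecedent <= 2, single consequent) rule directly."""
    n = len(transactions)
    rows = [set(t) for t in transactions]
    universe = sorted(set().union(*rows)) if rows else []
    out = {}
    for c in universe:
        for ant_size in (1, 2):
            for ant in itertools.combinations([i for i in universe if i != c],
                                              ant_size):
                n_a = sum(1 for r in rows if set(ant) <= r)
                if n_a == 0:
                    continue
                n_r = sum(1 for r in rows if set(ant) <= r and c in r)
                n_c = sum(1 for r in rows if c in r)
                supp = n_r / n
                conf = n_r / n_a
                lift = conf * n / n_c if n_c else 0.0
                if (supp >= min_supp - 1e-12 and conf >= min_conf - 1e-12
                        and lift >= min_lift - 1e-12):
                    out[(frozenset(ant), c)] = (supp, conf, lift)
    return out


EXAMPLE_D = [{0, 1}, {0, 1, 2}, {0, 2}, {1}]   # {AB, ABC, AC, B}


class TestApriori:
    def test_hand_counted_supports(self):
        ds = dataset_from_itemsets(EXAMPLE_D)
        freq = apriori(ds, min_supp=0.2, max_size=3)
        n = 4
        assert freq[frozenset({0})] / n == 0.75
        assert freq[frozenset({0, 1})] / n == 0.5
        assert freq[frozenset({0, 1, 2})] / n == 0.25

    def test_min_supp_one_keeps_universal_itemsets(self):
        ds = dataset_from_itemsets([{0, 1}, {0, 1, 2}, {0, 1}])
        freq = apriori(ds, min_supp=1.0)
        assert set(freq) == {frozenset({0}), frozenset({1}),
                             frozenset({0, 1})}

    def test_nonpositive_min_supp_rejected(self):
        ds = dataset_from_itemsets(EXAMPLE_D)
        with pytest.raises(ConfigError):
            apriori(ds, min_supp=0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_items = int(rng.integers(4, 13))
        n_rows = int(rng.integers(10, 201))
        p = rng.uniform(0.05, 0.5)
        transactions = [set(np.flatnonzero(rng.random(n_items) < p))
                        for _ in range(n_rows)]
        min_supp = float(rng.choice([0.01, 0.05, 0.2]))
        ds = dataset_from_itemsets(transactions, n_items=n_items)
        freq = apriori(ds, min_supp=min_supp, max_size=3)
        oracle = brute_force_itemsets(transactions, min_supp, 3)
        assert freq == oracle

    def test_anti_monotonicity(self):
        rng = np.random.default_rng(17)
        transactions = [set(np.flatnonzero(rng.random(10) < 0.4))
                        for _ in range(60)]
        ds = dataset_from_itemsets(transactions, n_items=10)
        freq = apriori(ds, min_supp=0.05, max_size=3)
        for itemset, cnt in freq.items():
            for item in itemset:
                sub = itemset - {item}
                if sub:
                    assert sub in freq and freq[sub] >= cnt


class TestGenerateRules:
    def test_low_confidence_rejected(self):
        ds = dataset_from_itemsets(EXAMPLE_D)
        freq = apriori(ds, min_supp=0.2)
        rules = generate_rules(freq, ds, min_conf=0.75, min_lift=0.0)
        pairs = {(tuple(i.metric for i in r.antecedent), r.consequent.metric)
                 for r in rules}
        assert (("i0",), "i1") not in pairs    # A=>B has conf 2/3

    def test_boundary_thresholds_inclusive(self):
        # two items always co-occur in half the transactions
        ds = dataset_from_itemsets([{0, 1}, {0, 1}, {2}, {3}])
        freq = apriori(ds, min_supp=0.25)
        rules = generate_rules(freq, ds, min_conf=0.75, min_lift=2.0)
        got = {(r.antecedent[0].metric, r.consequent.metric,
                r.confidence, r.lift) for r in rules}
        assert ("i0", "i1", 1.0, 2.0) in got   # lift exactly 2.0 retained

    def test_exact_confidence_boundary_survives(self):
        # conf exactly 3/4 = 0.75 must survive the inclusive threshold
        ds = dataset_from_itemsets([{0, 1}, {0, 1}, {0, 1}, {0}, {2}, {2},
                                    {2}, {2}])
        freq = apriori(ds, min_supp=0.1)
        rules = generate_rules(freq, ds, min_conf=0.75, min_lift=1.5)
        confs = {(r.antecedent[0].metric, r.consequent.metric): r.confidence
                 for r in rules}
        assert confs[("i0", "i1")] == 0.75

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_rule_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_items = int(rng.integers(4, 11))
        n_rows = int(rng.integers(8, 120))
        transactions = [set(np.flatnonzero(rng.random(n_items) < 0.35))
                        for _ in range(n_rows)]
        ds = dataset_from_itemsets(transactions, n_items=n_items)
        freq = apriori(ds, min_supp=0.01, max_size=3)
        rules = generate_rules(freq, ds, min_conf=0.6, min_lift=1.2,
                               min_supp=0.01)
        got = {(frozenset(ds.table.item_id(i) for i in r.antecedent),
                ds.table.item_id(r.consequent)):
               (r.support, r.confidence, r.lift) for r in rules}
        oracle = brute_force_rules(transactions, 0.01, 0.6, 1.2)
        assert set(got) == set(oracle)
        for key in got:
            assert got[key] == pytest.approx(oracle[key])

    def test_contract_properties(self):
        rng = np.random.default_rng(7)
        transactions = [set(np.flatnonzero(rng.random(9) < 0.4))
                        for _ in range(50)]
        ds = dataset_from_itemsets(transactions, n_items=9)
        rules = generate_rules(apriori(ds, 0.05), ds, min_conf=0.3,
                               min_lift=0.5)
        assert rules
        for r in rules:
            assert 1 <= len(r.antecedent) <= 2
            assert r.support <= r.confidence + 1e-12
            assert r.consequent not in r.antecedent


class TestDiscretization:
    def make_table(self, **columns):
        return pd.DataFrame(columns)

    def test_equal_frequency_tertiles(self):
        col = attribute_column("sd", "awake", 0)
        table = self.make_table(**{col: np.arange(1.0, 10.0)})
        scheme = fit_discretization(table)
        labels = scheme.assign_labels(col, np.arange(1.0, 10.0))
        assert list(labels) == ["L1"] * 3 + ["L2"] * 3 + ["L3"] * 3

    def test_equal_interval_edges(self):
        col = attribute_column("hbgi", "awake", 0)
        vals = np.linspace(0.0, 3.0, 13)
        table = self.make_table(**{col: vals})
        scheme = fit_discretization(table)
        assert scheme.per_attribute[col].edges == pytest.approx((1.0, 2.0))
        labels = scheme.assign_labels(col, np.array([0.0, 0.5, 1.0, 1.5,
                                                     2.0, 2.5, 3.0]))
        assert list(labels) == ["L1", "L1", "L2", "L2", "L3", "L3", "L3"]

    @pytest.mark.parametrize("value,label", [
        (40.0, "severe low"), (53.9, "severe low"), (54.0, "low"),
        (60.0, "low"), (70.0, "normal"), (139.9, "normal"), (150.0, "high"),
        (180.0, "severe high"), (200.0, "severe high"), (260.0, "severe high"),
    ])
    def test_clinical_cutoffs(self, value, label):
        col = attribute_column("mean", "sleep", 0)
        table = self.make_table(**{col: np.array([80.0, 90.0])})
        scheme = fit_discretization(table)
        assert scheme.assign_labels(col, np.array([value]))[0] == label

    def test_constant_attribute_degenerates_to_middle(self):
        col = attribute_column("cv", "awake", 1)
        table = self.make_table(**{col: np.full(5, 3.3)})
        scheme = fit_discretization(table)
        labels = scheme.assign_labels(col, np.full(5, 3.3))
        assert set(labels) == {"L2"}

    def test_missing_values_produce_no_item(self):
        col = attribute_column("mage", "sleep", 0)
        table = self.make_table(**{col: [1.0, np.nan, 3.0, 5.0]})
        ds = transform(table, fit_discretization(table))
        assert ds.matrix[1].sum() == 0
        assert ds.matrix[0].sum() == 1

    def test_transformation_table_bijective(self):
        col_a = attribute_column("mean", "awake", 1)
        col_b = attribute_column("lbgi", "awake", 0)
        table = self.make_table(**{col_a: [60.0, 100.0, 150.0],
                                   col_b: [0.1, 1.0, 5.0]})
        ds = transform(table, fit_discretization(table))
        for row in range(3):
            for item_id in np.flatnonzero(ds.matrix[row]):
                item = ds.table.item(item_id)
                assert ds.table.item_id(item) == item_id
                assert isinstance(item, Item)
        # at most one item per attribute per transaction
        for row in range(3):
            attrs = [ds.table.item(i).attribute
                     for i in np.flatnonzero(ds.matrix[row])]
            assert len(attrs) == len(set(attrs))


class TestAttributeTable:
    def test_day_triples_from_profiles(self, default_profiles):
        table = build_attribute_table(default_profiles)
        # 12 subjects x 14 days: days 2..13 have all three groups
        assert len(table) == 12 * 12
        assert attribute_column("lbgi", "awake", 1) in table.columns
        assert attribute_column("min", "sleep", 0) in table.columns
        assert attribute_column("mean", "awake", 0) in table.columns

    def test_gap_day_removes_spanning_triples(self, default_profiles):
        prof = default_profiles.copy()
        sid = prof["subject_id"].iloc[0]
        days = sorted(prof.loc[prof.subject_id == sid, "day_index"].unique())
        gap_day = days[5]
        pruned = prof[~((prof.subject_id == sid) & (prof.day_index == gap_day))]
        full = build_attribute_table(default_profiles)
        gapped = build_attribute_table(pruned)
        # the triple centred on the gap day and the one needing its awake
        # segment as day N-1 both disappear
        assert len(full) - len(gapped) == 2

    def test_column_name_round_trip(self):
        assert parse_attribute_column(attribute_column("j_index", "sleep", 1)) \
            == ("j_index", "sleep", 1)
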