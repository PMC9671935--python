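"""Quantitative association-rule mining of discretized GV profiles.

The numeric GV metrics are first discretized: glucose-level metrics
(mean, min, max, mge, mgn) by the fixed clinical cutoffs
``[0, 54, 70, 140, 180, 250]`` mg/dl with labels severe low / low /
normal / high / severe high; the variability metrics (sd, cv, tir,
LBGI, MAGE, J-index) into empirical tertiles (equal frequency, labels
L1 < L2 < L3); and HBGI into three equal-width intervals over its
observed range. Intervals are left-closed/right-open with the final
interval closed, so a glucose of exactly 70 mg/dl is "normal";
equal-frequency ties are assigned to the lower bin.

Each analysis row is a sleep-centred day-triple holding three attribute
groups — awake metrics of day N-1, sleep metrics of day N and awake
metrics of day N — so that mined rules can respect temporal order.
Every (attribute, interval) pair becomes one binary item via a
transformation table, and the resulting transaction dataset is mined
with Apriori under the study constraints: itemsets of at most 3 items,
minimum support 0.01, and rules with 1-2 antecedent items and a single
consequent at confidence >= 0.75 and lift >= 2.0 (thresholds
inclusive; support, confidence and lift are exact transaction-count
ratios).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, GvarmError
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

CLINICAL_EDGES = (0.0, 54.0, 70.0, 140.0, 180.0, 250.0)
CLINICAL_LABELS = ("severe low", "low", "normal", "high", "severe high")
TERTILE_LABELS = ("L1", "L2", "L3")

#: Default discretization method per GV metric.
DEFAULT_METHODS = {
    "mean": "clinical_cutoffs", "min": "clinical_cutoffs",
    "max": "clinical_cutoffs", "mge": "clinical_cutoffs",
    "mgn": "clinical_cutoffs",
    "sd": "equal_frequency", "cv": "equal_frequency",
    "tir": "equal_frequency", "lbgi": "equal_frequency",
    "j_index": "equal_frequency", "mage": "equal_frequency",
    "hbgi": "equal_interval",
}

#: (role, lag) of the three attribute groups of a day-triple row.
GROUPS = (("awake", 1), ("sleep", 0), ("awake", 0))


class Item(NamedTuple):
    """One binary item: a GV metric of a role/lag group in an interval."""

    metric: str
    role: str       # "awake" | "sleep"
    lag: int        # 0 = day N, 1 = day N-1
    label: str

    @property
    def attribute(self) -> tuple[str, str, int]:
        return (self.metric, self.role, self.lag)

    def __str__(self) -> str:
        day = "N-1" if self.lag else "N"
        return f"{self.metric}_{self.role}_{day}={self.label.replace(' ', '_')}"


def attribute_column(metric: str, role: str, lag: int) -> str:
    return f"{metric}__{role}__{lag}"


def parse_attribute_column(col: str) -> tuple[str, str, int]:
    metric, role, lag = col.split("__")
    return metric, role, int(lag)


def build_attribute_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """One row per sleep-centred day-triple of GV metric values.

    ``profiles`` has one row per (subject_id, day_index, role). A row is
    emitted for sleep day N only when the awake profile of day N-1
    (consecutive calendar date) and the awake profile of day N both
    exist; rows missing a whole group are dropped with a logged count.
    Columns are named ``metric__role__lag``.
    """
    idx = {(r.subject_id, r.day_index, r.role): r
           for r in profiles.itertuples(index=False)}
    rows, dropped = [], 0
    one_day = pd.Timedelta(days=1).to_pytimedelta()
    for (sid, day, role), rec in sorted(
            idx.items(), key=lambda kv: (kv[0][0], str(kv[0][1]), kv[0][2])):
        if role != "sleep":
            continue
        awake_prev = idx.get((sid, day - one_day, "awake"))
        awake_same = idx.get((sid, day, "awake"))
        if awake_prev is None or awake_same is None:
            dropped += 1
            continue
        row = {"subject_id": sid, "day_index": day}
        for (grp_role, lag), rec_g in zip(GROUPS, (awake_prev, rec, awake_same)):
            for metric in METRIC_NAMES:
                row[attribute_column(metric, grp_role, lag)] = getattr(rec_g, metric)
        rows.append(row)
    if dropped:
        logger.info("dropped %d sleep days missing an awake group", dropped)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AttributeScheme:
    method: str
    edges: tuple            # inner cut points (full edge list for clinical)
    labels: tuple[str, ...]
    degenerate: bool = False


@dataclass
class DiscretizationScheme:
    """Per-attribute discretization rules fitted on an attribute table."""

    per_attribute: dict[str, AttributeScheme]

    def assign_labels(self, column: str, values: np.ndarray) -> np.ndarray:
        """Map numeric values to interval labels (NaN maps to None)."""
        sch = self.per_attribute[column]
        values = np.asarray(values, dtype=float)
        out = np.empty(values.shape, dtype=object)
        out[:] = None
        ok = ~np.isnan(values)
        v = values[ok]
        if sch.degenerate:
            mid = sch.labels[len(sch.labels) // 2]
            out[ok] = mid
            return out
        if sch.method == "clinical_cutoffs":
            inner = np.asarray(sch.edges[1:-1])
            over = v > sch.edges[-1]
            if over.any():
                logger.warning("%s: %d values above %g clamped to %r",
                               column, int(over.sum()), sch.edges[-1],
                               sch.labels[-1])
            idx = np.searchsorted(inner, v, side="right")
        elif sch.method == "equal_frequency":
            # ties on a cut point fall into the lower bin
            idx = np.searchsorted(np.asarray(sch.edges), v, side="left")
        elif sch.method == "equal_interval":
            idx = np.searchsorted(np.asarray(sch.edges), v, side="right")
        else:
            raise GvarmError(f"unknown discretization method {sch.method!r}")
        idx = np.clip(idx, 0, len(sch.labels) - 1)
        out[ok] = np.asarray(sch.labels, dtype=object)[idx]
        return out


def fit_discretization(table: pd.DataFrame,
                       methods: dict[str, str] | None = None
                       ) -> DiscretizationScheme:
    """Fit per-attribute edges on an attribute table (pooled over rows).

    Clinical attributes use the fixed edges; equal-frequency attributes
    get tertile cut points from the pooled empirical distribution;
    equal-interval attributes get two equal-width cuts over the observed
    [min, max]. Constant attributes degenerate: every value is assigned
    the middle label with a warning.
    """
    methods = {**DEFAULT_METHODS, **(methods or {})}
    per_attribute = {}
    for col in table.columns:
        if col in ("subject_id", "day_index"):
            continue
        metric, _, _ = parse_attribute_column(col)
        method = methods[metric]
        vals = table[col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if method == "clinical_cutoffs":
            per_attribute[col] = AttributeScheme(method, CLINICAL_EDGES,
                                                 CLINICAL_LABELS)
            continue
        if vals.size == 0 or np.ptp(vals) == 0:
            logger.warning("%s: constant or empty attribute; middle label "
                           "assigned to all values", col)
            per_attribute[col] = AttributeScheme(method, (), TERTILE_LABELS,
                                                 degenerate=True)
            continue
        if method == "equal_frequency":
            e1, e2 = np.quantile(vals, [1 / 3, 2 / 3])
            if e1 == e2:
                logger.warning("%s: duplicate tertile edges collapsed", col)
                edges = (float(e1),)
                labels = ("L1", "L3")
            else:
                edges = (float(e1), float(e2))
                labels = TERTILE_LABELS
        elif method == "equal_interval":
            lo, hi = float(vals.min()), float(vals.max())
            edges = (lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3)
            labels = TERTILE_LABELS
        else:
            raise GvarmError(f"unknown discretization method {method!r}")
        per_attribute[col] = AttributeScheme(method, edges, labels)
    return DiscretizationScheme(per_attribute)


@dataclass
class TransformationTable:
    """Bijective mapping between item ids and (attribute, label) pairs."""

    items: tuple[Item, ...]

    def __post_init__(self):
        self._index = {item: i for i, item in enumerate(self.items)}
        if len(self._index) != len(self.items):
            raise GvarmError("transformation table items are not unique")

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: int) -> Item:
        return self.items[item_id]

    def item_id(self, item: Item) -> int:
        return self._index[item]


@dataclass
class TransactionDataset:
    """Binary item-presence matrix, one transaction per day-triple."""

    matrix: np.ndarray                  # bool, n_transactions x n_items
    table: TransformationTable
    transaction_ids: list               # (subject_id, day_index) per row

    @property
    def n_transactions(self) -> int:
        return self.matrix.shape[0]

    def support_count(self, item_ids) -> int:
        ids = list(item_ids)
        if not ids:
            return self.n_transactions
        return int(self.matrix[:, ids].all(axis=1).sum())

    def to_basket_lines(self) -> list[str]:
        return [" ".join(str(self.table.item(i))
                         for i in np.flatnonzero(row))
                for row in self.matrix]

    def to_frame(self) -> pd.DataFrame:
        cols = [str(item) for item in self.table.items]
        frame = pd.DataFrame(self.matrix.astype(int), columns=cols)
        frame.insert(0, "subject_id", [t[0] for t in self.transaction_ids])
        frame.insert(1, "day_index", [t[1] for t in self.transaction_ids])
        return frame


def transform(table: pd.DataFrame, scheme: DiscretizationScheme
              ) -> TransactionDataset:
    """Discretize an attribute table into a binary transaction dataset.

    Missing metric values produce no item, so each attribute sets at
    most one item per transaction. All-zero rows are kept but flagged
    with a warning.
    """
    value_cols = [c for c in table.columns if c not in ("subject_id", "day_index")]
    labelled = {c: scheme.assign_labels(c, table[c].to_numpy(dtype=float))
                for c in value_cols}
    items: list[Item] = []
    for c in value_cols:
        metric, role, lag = parse_attribute_column(c)
        for label in scheme.per_attribute[c].labels:
            items.append(Item(metric, role, lag, label))
    ttable = TransformationTable(tuple(items))
    n = len(table)
    matrix = np.zeros((n, len(items)), dtype=bool)
    for c in value_cols:
        metric, role, lag = parse_attribute_column(c)
        labels = labelled[c]
        for r in range(n):
            if labels[r] is not None:
                matrix[r, ttable.item_id(Item(metric, role, lag, labels[r]))] = True
    empty = int((~matrix.any(axis=1)).sum())
    if empty:
        logger.warning("%d all-missing transactions (all-zero rows)", empty)
    ids = list(zip(table.get("subject_id", pd.Series([""] * n)),
                   table.get("day_index", pd.Series(range(n)))))
    return TransactionDataset(matrix=matrix, table=ttable, transaction_ids=ids)


def dataset_from_itemsets(transactions: list, n_items: int | None = None,
                          items: tuple[Item, ...] | None = None
                          ) -> TransactionDataset:
    """Build a :class:`TransactionDataset` from explicit item-id sets.

    Convenience constructor for tests and for basket-format input.
    """
    if items is None:
        if n_items is None:
            n_items = max((max(t) for t in transactions if t), default=-1) + 1
        items = tuple(Item(f"i{i}", "awake", 0, "L1") for i in range(n_items))
    matrix = np.zeros((len(transactions), len(items)), dtype=bool)
    for r, t in enumerate(transactions):
        for i in t:
            matrix[r, i] = True
    return TransactionDataset(matrix=matrix, table=TransformationTable(items),
                              transaction_ids=list(enumerate(transactions)))


def apriori(dataset: TransactionDataset, min_supp: float = 0.01,
            max_size: int = 3) -> dict[frozenset, int]:
    """Level-wise Apriori: all itemsets of size <= max_size with
    support >= min_supp, returned as ``{itemset: transaction count}``.

    Supports are exact fractions ``count / n``; the threshold comparison
    is performed on exact rationals so boundary supports survive.
    """
    if min_supp <= 0:
        raise ConfigError("min_supp", "must be positive")
    if dataset.n_transactions == 0:
        raise GvarmError("transaction dataset is empty")
    n = dataset.n_transactions
    min_frac = Fraction(min_supp).limit_denominator(10 ** 12)
    # smallest count c with c/n >= min_supp
    min_count = max(1, math.ceil(min_frac * n))
    matrix = dataset.matrix
    counts1 = matrix.sum(axis=0)
    frequent: dict[frozenset, int] = {}
    level = []
    for i in range(matrix.shape[1]):
        if counts1[i] >= min_count:
            key = (i,)
            frequent[frozenset(key)] = int(counts1[i])
            level.append(key)
    k = 1
    while level and k < max_size:
        k += 1
        candidates = _candidates(level, frequent)
        level = []
        for cand in candidates:
            cnt = int(matrix[:, cand].all(axis=1).sum())
            if cnt >= min_count:
                frequent[frozenset(cand)] = cnt
                level.append(cand)
        level.sort()
    return frequent


def _candidates(level: list[tuple], frequent: dict[frozenset, int]
                ) -> list[tuple]:
    """Join sorted (k-1)-tuples sharing a (k-2)-prefix; prune by subsets."""
    out = []
    level = sorted(level)
    by_prefix: dict[tuple, list[int]] = {}
    for t in level:
        by_prefix.setdefault(t[:-1], []).append(t[-1])
    for prefix, lasts in by_prefix.items():
        lasts.sort()
        for a, b in itertools.combinations(lasts, 2):
            cand = prefix + (a, b)
            if all(frozenset(cand[:i] + cand[i + 1:]) in frequent
                   for i in range(len(cand))):
                out.append(cand)
    return out


@dataclass(frozen=True)
class CandidateRule:
    """An association rule X => Y with its three interest measures."""

    antecedent: tuple[Item, ...]
    consequent: Item
    support: float
    confidence: float
    lift: float
    n_rule: int          # transactions containing X union Y
    n_antecedent: int
    n_consequent: int
    n_total: int

    def __str__(self) -> str:
        lhs = ", ".join(str(i) for i in self.antecedent)
        return f"{{{lhs}}} => {{{self.consequent}}}"


def generate_rules(frequent: dict[frozenset, int], dataset: TransactionDataset,
                   min_conf: float = 0.75, min_lift: float = 2.0,
                   min_supp: float = 0.01, max_antecedent: int = 2
                   ) -> list[CandidateRule]:
    """Generate rules with 1-2 antecedent items and one consequent item.

    Confidence and lift thresholds are inclusive and compared on exact
    rationals. Rules are returned in a canonical deterministic order.
    """
    n = dataset.n_transactions
    min_conf_f = Fraction(min_conf).limit_denominator(10 ** 12)
    min_lift_f = Fraction(min_lift).limit_denominator(10 ** 12)
    min_supp_f = Fraction(min_supp).limit_denominator(10 ** 12)
    rules = []
    for itemset, cnt in frequent.items():
        if len(itemset) < 2 or len(itemset) > max_antecedent + 1:
            continue
        if Fraction(cnt, n) < min_supp_f:
            continue
        for consequent in sorted(itemset):
            antecedent = frozenset(itemset - {consequent})
            cnt_a = frequent.get(antecedent)
            if cnt_a is None:
                cnt_a = dataset.support_count(antecedent)
            cnt_c = frequent.get(frozenset({consequent}))
            if cnt_c is None:
                cnt_c = dataset.support_count([consequent])
            conf = Fraction(cnt, cnt_a)
            if conf < min_conf_f:
                continue
            lift = Fraction(cnt * n, cnt_a * cnt_c)
            if lift < min_lift_f:
                continue
            rules.append(CandidateRule(
                antecedent=tuple(dataset.table.item(i)
                                 for i in sorted(antecedent)),
                consequent=dataset.table.item(consequent),
                support=cnt / n, confidence=float(conf), lift=float(lift),
                n_rule=cnt, n_antecedent=cnt_a, n_consequent=cnt_c, n_total=n,
            ))
    rules.sort(key=lambda r: (len(r.antecedent), r.antecedent, r.consequent))
    return rules


def rule_item_ids(rule: CandidateRule, dataset: TransactionDataset
                  ) -> tuple[list[int], int]:
    ant = [dataset.table.item_id(i) for i in rule.antecedent]
    return ant, dataset.table.item_id(rule.consequent)
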