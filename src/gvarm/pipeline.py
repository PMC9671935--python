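"""End-to-end analysis pipeline.

Orchestrates: segmentation -> GV profiles -> descriptive statistics ->
repeated-measures correlation matrices -> discretization ->
transaction mining -> rule post-filtering, from a single configuration,
with per-stage row counts recorded in the run metadata. All randomness
flows from the single config seed and intermediate artifacts are
written to disk so each stage is independently inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .io import (DailySegments, read_cgm_cohort, read_sleep_cohort,
                 segment_days, build_pairs)
from .metrics import METRIC_NAMES, profile
from .qarm import (TransactionDataset, apriori, build_attribute_table,
                   fit_discretization, generate_rules, transform)
from .rule_filter import apply_postfilter, scored_rules_frame
from .stats import mann_whitney, rmcorr_matrix, significance_stars
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Exactly one of ``cohort`` (synthetic generation) or the pair
    ``cgm_path``/``sleep_path`` (recorded data) must be set.
    """

    cohort: CohortConfig | None = None
    cgm_path: str | None = None
    sleep_path: str | None = None
    k: float = 1.0
    min_coverage: float = 0.7
    mage_direction: str = "symmetric"
    min_supp: float = 0.01
    min_conf: float = 0.75
    min_lift: float = 2.0
    max_size: int = 3
    alpha: float = 0.05
    mi_min: float = 0.3
    kappa_min: float = 0.3
    prune_redundant: bool = False
    rmcorr_r_min: float = 0.4
    rmcorr_alpha: float = 0.05
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort is None) == (self.cgm_path is None):
            raise ConfigError("cohort",
                              "set exactly one of cohort or cgm_path/sleep_path")
        if self.cgm_path is not None and self.sleep_path is None:
            raise ConfigError("sleep_path", "required with cgm_path")
        for name, lo, hi in (("min_supp", 0.0, 1.0), ("min_conf", 0.0, 1.0),
                             ("alpha", 0.0, 1.0), ("mi_min", 0.0, 1.0),
                             ("kappa_min", -1.0, 1.0),
                             ("min_coverage", 0.0, 1.0)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(name, f"must lie in [{lo}, {hi}]")
        if self.min_supp <= 0:
            raise ConfigError("min_supp", "must be positive")
        if self.min_lift < 0:
            raise ConfigError("min_lift", "must be non-negative")
        if self.cohort is not None:
            self.cohort.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            sub = raw["cohort"]
            if isinstance(sub.get("days_per_subject"), list):
                sub["days_per_subject"] = tuple(sub["days_per_subject"])
            raw["cohort"] = CohortConfig(**sub)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d


@dataclass
class AnalysisReport:
    """All pipeline outputs plus run metadata."""

    profiles: pd.DataFrame
    descriptives: pd.DataFrame
    rmcorr_type1: pd.DataFrame
    rmcorr_type2: pd.DataFrame
    transactions: TransactionDataset | None
    candidate_rules: pd.DataFrame
    scored_rules: pd.DataFrame
    ranked_rules: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(out / "gv_profiles.csv", index=False)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.rmcorr_type1.to_csv(out / "rmcorr_type1.csv", index=False)
        self.rmcorr_type2.to_csv(out / "rmcorr_type2.csv", index=False)
        if self.transactions is not None:
            self.transactions.to_frame().to_csv(out / "transactions.csv",
                                                index=False)
            (out / "transactions.basket").write_text(
                "\n".join(self.transactions.to_basket_lines()) + "\n")
        self.candidate_rules.to_csv(out / "candidate_rules.csv", index=False)
        self.scored_rules.to_csv(out / "scored_rules.csv", index=False)
        self.ranked_rules.to_csv(out / "ranked_rules.csv", index=False)
        (out / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, default=str) + "\n")


def profiles_from_segments(days: list[DailySegments], k: float = 1.0,
                           mage_direction: str = "symmetric") -> pd.DataFrame:
    """GV profiles of all complete segments, one row per
    (subject, day, role); incomplete segments are skipped with a warning.
    """
    rows = []
    skipped = 0
    for d in days:
        for role, seg, ok in (("sleep", d.sleep, d.sleep_complete),
                              ("awake", d.awake, d.awake_complete)):
            if not ok:
                skipped += 1
                continue
            prof = profile(seg.to_numpy(), k, segment_role=role,
                           day_index=d.day_index, subject_id=d.subject_id,
                           mage_direction=mage_direction)
            rows.append({"subject_id": d.subject_id, "day_index": d.day_index,
                         "role": role, **prof.metric_dict(), "n": prof.n})
    if skipped:
        logger.warning("skipped %d incomplete segments", skipped)
    return pd.DataFrame(rows)


def summarize_descriptives(profiles: pd.DataFrame) -> pd.DataFrame:
    """Awake-vs-sleep summary per metric: medians, quartiles,
    Mann-Whitney U, two-sided p and significance stars.

    ``display_factor`` is 100 for HBGI (plot-backing convention to make
    its small values visible next to LBGI) and 1 elsewhere; it scales
    only the ``*_display`` columns, never the test.
    """
    rows = []
    for metric in METRIC_NAMES:
        awake = profiles.loc[profiles["role"] == "awake", metric].dropna()
        sleep = profiles.loc[profiles["role"] == "sleep", metric].dropna()
        u, p = mann_whitney(awake, sleep)
        factor = 100.0 if metric == "hbgi" else 1.0
        rows.append({
            "metric": metric,
            "awake_median": awake.median(), "awake_q1": awake.quantile(0.25),
            "awake_q3": awake.quantile(0.75),
            "sleep_median": sleep.median(), "sleep_q1": sleep.quantile(0.25),
            "sleep_q3": sleep.quantile(0.75),
            "n_awake": len(awake), "n_sleep": len(sleep),
            "U": u, "p": p, "stars": significance_stars(p),
            "display_factor": factor,
            "awake_median_display": awake.median() * factor,
            "sleep_median_display": sleep.median() * factor,
        })
    return pd.DataFrame(rows)


def candidate_rules_frame(rules) -> pd.DataFrame:
    if not rules:
        return pd.DataFrame(columns=["antecedent", "consequent", "supp",
                                     "conf", "lift"])
    return pd.DataFrame([{
        "antecedent": "; ".join(str(i) for i in r.antecedent),
        "consequent": str(r.consequent),
        "supp": r.support, "conf": r.confidence, "lift": r.lift,
    } for r in rules])


def run(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage in order and return the assembled report.

    Identical config and seed give identical output; every discarded
    record is accounted for in the metadata stage counts.
    """
    config.validate()
    meta: dict = {"gvarm_version": __version__, "seed": config.seed,
                  "config": config.to_dict(), "stages": {}}

    if config.cohort is not None:
        cohort_cfg = config.cohort
        if cohort_cfg.seed != config.seed:
            cohort_cfg = CohortConfig(**{**cohort_cfg.to_dict(),
                                         "days_per_subject":
                                         cohort_cfg.days_per_subject,
                                         "seed": config.seed})
        cohort = generate_cohort(cohort_cfg)
        subjects = {sid: pair for sid, pair in cohort.subjects.items()}
        logger.info("generated synthetic cohort: %d subjects", len(subjects))
    else:
        cgm = read_cgm_cohort(config.cgm_path)
        sleep = read_sleep_cohort(config.sleep_path)
        subjects = {sid: (cgm[sid], sleep.get(sid, []))
                    for sid in sorted(cgm)}
        logger.info("loaded cohort: %d subjects", len(subjects))
    meta["stages"]["subjects"] = len(subjects)
    meta["stages"]["readings"] = int(sum(len(s) for s, _ in subjects.values()))

    all_days: list[DailySegments] = []
    for sid in sorted(subjects):
        series, episodes = subjects[sid]
        all_days.extend(segment_days(series, episodes, config.min_coverage))
    type1, type2 = build_pairs_cohort(all_days)
    meta["stages"]["days_segmented"] = len(all_days)
    meta["stages"]["type1_pairs"] = len(type1)
    meta["stages"]["type2_pairs"] = len(type2)

    profiles = profiles_from_segments(all_days, config.k,
                                      config.mage_direction)
    meta["stages"]["profiles"] = len(profiles)

    descriptives = summarize_descriptives(profiles)
    rm1 = rmcorr_matrix(profiles, "type1", config.rmcorr_r_min,
                        config.rmcorr_alpha)
    rm2 = rmcorr_matrix(profiles, "type2", config.rmcorr_r_min,
                        config.rmcorr_alpha)
    meta["stages"]["rmcorr_cells_kept"] = int(rm1["kept"].sum()
                                              + rm2["kept"].sum())

    attr_table = build_attribute_table(profiles)
    meta["stages"]["day_triples"] = len(attr_table)
    if len(attr_table) == 0:
        logger.warning("no usable day-triples; rule mining skipped")
        transactions = None
        rules = []
        scored = []
    else:
        scheme = fit_discretization(attr_table)
        transactions = transform(attr_table, scheme)
        frequent = apriori(transactions, config.min_supp, config.max_size)
        rules = generate_rules(frequent, transactions, config.min_conf,
                               config.min_lift, config.min_supp,
                               max_antecedent=config.max_size - 1)
        scored = apply_postfilter(rules, transactions, config.alpha,
                                  config.mi_min, config.kappa_min,
                                  config.prune_redundant)
        meta["stages"]["frequent_itemsets"] = len(frequent)
    meta["stages"]["candidate_rules"] = len(rules)
    scored_df = scored_rules_frame(scored)
    ranked = (scored_df[scored_df["survives"]]
              .sort_values("rank").reset_index(drop=True)
              if len(scored_df) else scored_df)
    meta["stages"]["surviving_rules"] = int(len(ranked))

    report = AnalysisReport(
        profiles=profiles, descriptives=descriptives,
        rmcorr_type1=rm1, rmcorr_type2=rm2,
        transactions=transactions,
        candidate_rules=candidate_rules_frame(rules),
        scored_rules=scored_df, ranked_rules=ranked, metadata=meta)
    if config.out_dir is not None:
        report.write(config.out_dir)
        logger.info("report written to %s", config.out_dir)
    return report


def build_pairs_cohort(all_days: list[DailySegments]):
    """Apply :func:`gvarm.io.build_pairs` per subject and concatenate."""
    type1, type2 = [], []
    by_subject: dict[str, list[DailySegments]] = {}
    for d in all_days:
        by_subject.setdefault(d.subject_id, []).append(d)
    for sid in sorted(by_subject):
        t1, t2 = build_pairs(by_subject[sid])
        type1.extend(t1)
        type2.extend(t2)
    return type1, type2
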