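"""Repeated-measures correlation and Mann-Whitney descriptive tests.

CGM cohorts are nested: each participant contributes many subject-days,
so ordinary Pearson correlation across pooled subject-days conflates
between- and within-subject association. The repeated-measures
correlation (rmcorr) removes each subject's own mean from both variables
and estimates the common within-subject slope — the analysis-of-
covariance formulation with subject indicator covariates. Degrees of
freedom are ``n_obs - n_subjects - 1`` and the p-value comes from the F
statistic with ``(1, df)`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GvarmError, UndefinedStatisticError
from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

#: Significance star bins used for descriptive boxplot annotations.
STAR_BINS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    n_obs: int
    n_subjects: int


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Repeated-measures correlation of paired observations.

    ``subjects`` labels each row; rows with missing ``x`` or ``y`` are
    dropped pairwise with a logged count. Requires at least two
    subjects with two or more (complete) observations each and at least
    one residual degree of freedom.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(subjects) == len(x) == len(y)):
        raise GvarmError("subjects, x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if (~ok).sum():
        logger.debug("rmcorr: dropped %d rows with missing values",
                     int((~ok).sum()))
    subjects, x, y = subjects[ok], x[ok], y[ok]
    frame = pd.DataFrame({"s": subjects, "x": x, "y": y})
    counts = frame.groupby("s").size()
    frame = frame[frame["s"].isin(counts[counts >= 2].index)]
    n_subjects = frame["s"].nunique()
    n_obs = len(frame)
    if n_subjects < 2:
        raise UndefinedStatisticError(
            "rmcorr needs at least 2 subjects with >= 2 observations")
    df = n_obs - n_subjects - 1
    if df < 1:
        raise UndefinedStatisticError("rmcorr has no residual degrees of freedom")
    xc = frame["x"] - frame.groupby("s")["x"].transform("mean")
    yc = frame["y"] - frame.groupby("s")["y"].transform("mean")
    sxx = float((xc ** 2).sum())
    syy = float((yc ** 2).sum())
    if sxx == 0 or syy == 0:
        raise UndefinedStatisticError(
            "rmcorr undefined: a variable is constant within every subject")
    r = float((xc * yc).sum() / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        p = 0.0
    else:
        f_stat = r ** 2 / (1.0 - r ** 2) * df
        p = float(sps.f.sf(f_stat, 1, df))
    return RmcorrResult(r=r, df=df, p=p, n_obs=n_obs, n_subjects=n_subjects)


def _strength(r: float) -> str:
    a = abs(r)
    if a > 0.6:
        return "strong"
    if a > 0.4:
        return "moderate"
    return "weak"


def paired_metric_table(profiles: pd.DataFrame, pairing: str) -> pd.DataFrame:
    """Join awake and sleep GV profiles into one row per pair.

    ``profiles`` has one row per (subject_id, day_index, role) with the
    12 metric columns. ``pairing="type1"`` joins awake metrics of day
    N-1 (consecutive calendar dates) with sleep metrics of day N;
    ``pairing="type2"`` joins sleep and awake metrics of the same day.
    Awake columns are suffixed ``_awake``, sleep columns ``_sleep``.
    """
    if pairing not in ("type1", "type2"):
        raise GvarmError(f"unknown pairing {pairing!r}")
    cols = ["subject_id", "day_index", *METRIC_NAMES]
    awake = profiles.loc[profiles["role"] == "awake", cols].copy()
    sleep = profiles.loc[profiles["role"] == "sleep", cols].copy()
    if pairing == "type1":
        one_day = pd.Timedelta(days=1).to_pytimedelta()
        awake = awake.assign(day_index=awake["day_index"].map(lambda d: d + one_day))
    merged = sleep.merge(awake, on=["subject_id", "day_index"],
                         suffixes=("_sleep", "_awake"))
    return merged


def rmcorr_matrix(profiles: pd.DataFrame, pairing: str,
                  r_min: float = 0.4, alpha: float = 0.05,
                  bh_correct: bool = False) -> pd.DataFrame:
    """All sleep-metric x awake-metric rmcorr values for one pairing.

    Returns a long-format frame with one row per metric pair (r, df, p,
    n_obs, n_subjects, kept, strength). ``kept`` marks cells that clear
    the reporting filter ``p < alpha`` and ``|r| > r_min``; strength is
    annotated as moderate (0.4 < |r| <= 0.6) or strong (|r| > 0.6).
    ``bh_correct`` optionally applies Benjamini-Hochberg across the
    matrix before filtering (off by default: cells are reported at raw
    p-values).
    """
    table = paired_metric_table(profiles, pairing)
    rows = []
    for sm in METRIC_NAMES:
        for am in METRIC_NAMES:
            try:
                res = rmcorr(table["subject_id"],
                             table[f"{am}_awake"], table[f"{sm}_sleep"])
            except UndefinedStatisticError:
                continue
            rows.append({
                "sleep_metric": sm, "awake_metric": am, "pairing": pairing,
                "r": res.r, "df": res.df, "p": res.p,
                "n_obs": res.n_obs, "n_subjects": res.n_subjects,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(columns=["sleep_metric", "awake_metric", "pairing",
                                    "r", "df", "p", "n_obs", "n_subjects",
                                    "p_reported", "kept", "strength"])
        return out
    if bh_correct:
        out["p_reported"] = _benjamini_hochberg(out["p"].to_numpy())
    else:
        out["p_reported"] = out["p"]
    out["kept"] = (out["p_reported"] < alpha) & (out["r"].abs() > r_min)
    out["strength"] = out["r"].map(_strength)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``a`` versus ``b``.

    Uses the exact null distribution for small samples without ties and
    the tie-corrected normal approximation otherwise. Returns
    ``(U, p)`` where U counts pairs won by ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise GvarmError("mann_whitney requires non-empty samples")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    """Boxplot annotation bins: ns, *, **, ***, **** by p-value."""
    for cut, stars in STAR_BINS:
        if p <= cut:
            return stars
    return "ns"
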