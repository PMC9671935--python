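"""Short-term within-day glycemic variability (GV) metrics.

All operations act on a one-dimensional array of interstitial glucose
readings in mg/dl taken from a single awake or in-sleep segment. Twelve
metrics are computed: mean, sd, max, min, cv, time-in-range (tir), mean
glucose outside/inside range (mge/mgn), the low and high blood glucose
risk indices (LBGI/HBGI), the mean amplitude of glycemic excursions
(MAGE) and the J-index.

The target range used by ``tir``/``mge``/``mgn`` is adaptive: it is
``mean - k*sd`` to ``mean + k*sd`` of the segment itself (``k`` defaults
to 1) rather than the fixed clinical 70-180 mg/dl band, so that the
range tracks each person's own glucose baseline. LBGI/HBGI rest on the
symmetrizing risk transform ``r(g) = 1.509*((ln g)^1.084 - 5.381)``,
whose negative branch captures hypoglycemic risk and positive branch
hyperglycemic risk; each index is the mean of ``10*r(g)^2`` over the
corresponding branch, with the full segment length as denominator.

``mge``, ``mgn`` and ``mage`` can be undefined (no reading outside the
range, no qualifying excursion, ...); undefined values are returned as
``nan`` and must be propagated as missing downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import EmptyInputError, GvarmError

logger = logging.getLogger(__name__)

#: Coefficients of the symmetrizing glucose risk transform (glucose in mg/dl).
RISK_SCALE = 1.509
RISK_EXPONENT = 1.084
RISK_OFFSET = 5.381

#: Glucose value (mg/dl) at which the risk score crosses zero.
RISK_ZERO_MGDL = float(math.exp(RISK_OFFSET ** (1.0 / RISK_EXPONENT)))

#: Canonical metric order used in tables and discretization.
METRIC_NAMES = (
    "mean", "sd", "max", "min", "cv", "tir",
    "mge", "mgn", "lbgi", "hbgi", "mage", "j_index",
)


def _as_values(segment) -> np.ndarray:
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise EmptyInputError("glucose segment is empty")
    return x


def basic_stats(segment) -> tuple[float, float, float, float, float]:
    """Return ``(mean, sd, max, min, cv)`` of a segment.

    ``sd`` is the sample standard deviation (n-1 denominator); for a
    single reading it is 0 by convention. ``cv`` is in percent.
    """
    x = _as_values(segment)
    mean = float(x.mean())
    if x.size == 1:
        logger.debug("single-reading segment: sd set to 0 by convention")
        sd = 0.0
    else:
        sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return mean, sd, float(x.max()), float(x.min()), cv


def adaptive_range(mean: float, sd: float, k: float = 1.0) -> tuple[float, float]:
    """Personalised target range ``(G_L, G_H) = (mean - k*sd, mean + k*sd)``."""
    if sd < 0:
        raise GvarmError("sd must be non-negative")
    return mean - k * sd, mean + k * sd


def tir(segment, k: float = 1.0) -> float:
    """Percentage of readings inside the adaptive range (bounds inclusive)."""
    x = _as_values(segment)
    mean, sd, _, _, _ = basic_stats(x)
    g_l, g_h = adaptive_range(mean, sd, k)
    inside = (x >= g_l) & (x <= g_h)
    return 100.0 * inside.sum() / x.size


def mge_mgn(segment, k: float = 1.0) -> tuple[float, float]:
    """Mean glucose strictly outside / inside the adaptive range.

    Either value is ``nan`` when no reading falls on that side; together
    with the inclusive ``tir`` bounds every reading is counted exactly
    once as inside or outside.
    """
    x = _as_values(segment)
    mean, sd, _, _, _ = basic_stats(x)
    g_l, g_h = adaptive_range(mean, sd, k)
    outside = (x < g_l) | (x > g_h)
    mge = float(x[outside].mean()) if outside.any() else float("nan")
    mgn = float(x[~outside].mean()) if (~outside).any() else float("nan")
    return mge, mgn


def risk(g):
    """Symmetrized glucose risk score ``1.509*((ln g)^1.084 - 5.381)``.

    Accepts a scalar or array of positive glucose values in mg/dl.
    Negative scores indicate hypoglycemic risk, positive hyperglycemic.
    """
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr <= 0):
        raise GvarmError("glucose must be positive for the risk transform")
    r = RISK_SCALE * (np.log(g_arr) ** RISK_EXPONENT - RISK_OFFSET)
    return float(r) if np.isscalar(g) or g_arr.ndim == 0 else r


def lbgi(segment) -> float:
    """Low blood glucose index: mean of ``10*r(g)^2`` over readings with
    negative risk, denominator the full segment length."""
    x = _as_values(segment)
    r = risk(x)
    rl = np.where(r < 0, 10.0 * r ** 2, 0.0)
    return float(rl.mean())


def hbgi(segment) -> float:
    """High blood glucose index: mirror of :func:`lbgi` for positive risk."""
    x = _as_values(segment)
    r = risk(x)
    rh = np.where(r > 0, 10.0 * r ** 2, 0.0)
    return float(rh.mean())


def mage(segment, k: float = 1.0, direction: str = "symmetric") -> float:
    """Mean amplitude of glycemic excursions.

    Turning points are located by sign changes of the first differences
    after collapsing plateaus; amplitudes are measured between
    consecutive alternating extrema (segment endpoints anchor the first
    and last excursion). Only amplitudes strictly greater than
    ``k * sd`` of the whole segment qualify. Returns ``nan`` when the
    segment has fewer than 3 readings, no interior turning point, or no
    qualifying excursion.

    ``direction="symmetric"`` (default) averages both rising and falling
    qualifying amplitudes; ``direction="first"`` is the classic variant
    that counts only excursions in the direction of the first
    qualifying one.
    """
    if direction not in ("symmetric", "first"):
        raise GvarmError(f"unknown MAGE direction {direction!r}")
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < 3:
        return float("nan")
    sd = float(x.std(ddof=1))
    # collapse plateaus so that runs of equal values cannot mask a turn
    keep = np.r_[True, np.diff(x) != 0]
    xc = x[keep]
    if xc.size < 3:
        return float("nan")
    s = np.sign(np.diff(xc))
    turns = np.where(s[1:] != s[:-1])[0] + 1
    if turns.size == 0:
        return float("nan")
    extrema = xc[np.r_[0, turns, xc.size - 1]]
    deltas = np.diff(extrema)
    amps = np.abs(deltas)
    qualifying = amps > k * sd
    if not qualifying.any():
        return float("nan")
    if direction == "first":
        rising = deltas > 0
        first_dir = rising[int(np.argmax(qualifying))]
        qualifying &= rising == first_dir
        if not qualifying.any():
            return float("nan")
    return float(amps[qualifying].mean())


def j_index(mean: float, sd: float) -> float:
    """J-index ``0.001 * (mean + sd)^2`` combining level and variability."""
    if sd < 0:
        raise GvarmError("sd must be non-negative")
    return 0.001 * (mean + sd) ** 2


@dataclass
class GVProfile:
    """The 12 GV metrics of one glucose segment.

    ``mge``, ``mgn`` and ``mage`` may be ``nan`` (undefined); ``g_l`` and
    ``g_h`` are the adaptive range bounds actually used.
    """

    mean: float
    sd: float
    max: float
    min: float
    cv: float
    tir: float
    mge: float
    mgn: float
    lbgi: float
    hbgi: float
    mage: float
    j_index: float
    n: int
    k: float = 1.0
    g_l: float = field(default=float("nan"))
    g_h: float = field(default=float("nan"))
    segment_role: str = ""
    day_index: object = None
    subject_id: str = ""

    def metric_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def profile(segment, k: float = 1.0, *, segment_role: str = "",
            day_index=None, subject_id: str = "",
            mage_direction: str = "symmetric") -> GVProfile:
    """Compute all 12 GV metrics on one segment and tag the result."""
    x = _as_values(segment)
    mean, sd, mx, mn, cv = basic_stats(x)
    g_l, g_h = adaptive_range(mean, sd, k)
    mge_v, mgn_v = mge_mgn(x, k)
    return GVProfile(
        mean=mean, sd=sd, max=mx, min=mn, cv=cv,
        tir=tir(x, k), mge=mge_v, mgn=mgn_v,
        lbgi=lbgi(x), hbgi=hbgi(x),
        mage=mage(x, k, direction=mage_direction),
        j_index=j_index(mean, sd),
        n=int(x.size), k=k, g_l=g_l, g_h=g_h,
        segment_role=segment_role, day_index=day_index, subject_id=subject_id,
    )
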