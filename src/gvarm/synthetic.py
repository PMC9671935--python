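"""Synthetic CGM + sleep-log cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
small cohort (~12 adults) wearing a 15-min CGM sensor for 4-14 days,
with glucose lower and flatter in sleep than awake, meal-driven
excursions in awake time, occasional nocturnal hypoglycemic dips, and a
tunable day-to-night coupling so that planted associations can be
recovered end-to-end.

Each reading is built as::

    baseline + day-level deviation + circadian term + meal/dip shape
             + AR(1) noise

The AR(1) noise (lag-1 coefficient 0.7 by default) makes the series
look CGM-like rather than white, which matters because MAGE and sd
degenerate on white noise. Meal excursions are raised-cosine bumps at
breakfast/lunch/dinner clock times; the deterministic shape terms are
centred within each awake/sleep window so that segment means are
controlled exactly by the configured levels. Readings are clipped to
the 40-400 mg/dl sensor reporting range and rounded to integers as real
sensors report.

Day-to-night coupling: each day's awake-segment mean deviates from the
cohort awake level by a Gaussian draw; the following night's sleep mean
deviation is correlated with it with coefficient ``coupling_gamma``.
A planted-rule scenario additionally shifts the awake day *after* a
severe-low night (min < 54 mg/dl) downward, so that its LBGI lands in
the cohort's top tertile — the association the rule miner should find.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import GlucoseSeries, SleepEpisode, write_cgm, write_sleep

#: Severe hypoglycemia threshold used by the planted-rule mechanism (mg/dl).
SEVERE_LOW_MGDL = 54.0

#: First day of every synthetic recording (arbitrary but fixed).
BASE_DATE = pd.Timestamp("2024-01-01")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Levels are in mg/dl. The within/between variance decomposition is
    explicit: ``awake_sd_mgdl``/``sleep_sd_mgdl`` are reading-level
    AR(1) noise standard deviations, ``awake_day_sd_mgdl``/
    ``sleep_day_sd_mgdl`` the between-day sd of segment means, and
    ``subject_sd_mgdl`` the between-subject baseline sd. Defaults target
    the awake/sleep glucose ranges reported for healthy young adults
    (awake mean ~93 +/- 10, sleep ~85 +/- 13, within-segment sd ~13 awake
    and ~7 in sleep).
    """

    n_subjects: int = 12
    days_per_subject: int | tuple[int, int] = (4, 14)
    sampling_minutes: int = 15
    awake_mean_mgdl: float = 93.0
    sleep_mean_offset_mgdl: float = -8.0
    awake_sd_mgdl: float = 8.0
    sleep_sd_mgdl: float = 6.0
    awake_day_sd_mgdl: float = 9.0
    sleep_day_sd_mgdl: float = 9.0
    subject_sd_mgdl: float = 4.0
    ar_coefficient: float = 0.7
    circadian_amplitude_mgdl: float = 2.0
    meal_excursion_amplitude_mgdl: float = 35.0
    meal_count_per_day: int = 3
    meal_halfwidth_minutes: float = 60.0
    hypo_dip_prob: float = 0.15
    hypo_dip_depth_mgdl: float = 25.0
    hypo_dip_halfwidth_minutes: float = 45.0
    coupling_gamma: float = 0.0
    sleep_onset_hour_mean: float = 23.5
    sleep_onset_hour_sd: float = 0.6
    sleep_duration_hours_mean: float = 7.5
    sleep_duration_hours_sd: float = 0.7
    nap_prob: float = 0.0
    planted_rule_strength: float = 0.0
    planted_shift_mgdl: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects", "must be at least 1")
        if isinstance(self.days_per_subject, (tuple, list)):
            lo, hi = self.days_per_subject
            if not (1 <= lo <= hi):
                raise ConfigError("days_per_subject", "range must satisfy 1 <= lo <= hi")
        elif self.days_per_subject < 1:
            raise ConfigError("days_per_subject", "must be at least 1")
        if self.sampling_minutes < 1 or 1440 % self.sampling_minutes != 0:
            raise ConfigError("sampling_minutes", "must divide 1440")
        if not 0.0 <= self.hypo_dip_prob <= 1.0:
            raise ConfigError("hypo_dip_prob", "must lie in [0, 1]")
        if not -1.0 <= self.coupling_gamma <= 1.0:
            raise ConfigError("coupling_gamma", "must lie in [-1, 1]")
        if not 0.0 <= self.planted_rule_strength <= 1.0:
            raise ConfigError("planted_rule_strength", "must lie in [0, 1]")
        for name in ("awake_sd_mgdl", "sleep_sd_mgdl", "awake_day_sd_mgdl",
                     "sleep_day_sd_mgdl", "subject_sd_mgdl",
                     "sleep_onset_hour_sd", "sleep_duration_hours_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be non-negative")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ConfigError("ar_coefficient", "must lie in [0, 1)")
        if not 0.0 <= self.nap_prob <= 1.0:
            raise ConfigError("nap_prob", "must lie in [0, 1]")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ConfigError("seed", "must be a non-negative 31-bit integer")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        if "days_per_subject" in raw and isinstance(raw["days_per_subject"], list):
            raw["days_per_subject"] = tuple(raw["days_per_subject"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["days_per_subject"], tuple):
            d["days_per_subject"] = list(d["days_per_subject"])
        return d


@dataclass
class Cohort:
    """A generated cohort: per-subject glucose series and sleep logs."""

    config: CohortConfig
    subjects: dict[str, tuple[GlucoseSeries, list[SleepEpisode]]]

    def write(self, out_dir) -> tuple[Path, Path]:
        """Write ``cgm.csv`` and ``sleep.csv`` in the native dialects."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cgm_path, sleep_path = out / "cgm.csv", out / "sleep.csv"
        write_cgm([s for s, _ in self.subjects.values()], cgm_path)
        write_sleep({sid: eps for sid, (_, eps) in self.subjects.items()},
                    sleep_path)
        return cgm_path, sleep_path


def _raised_cosine(minutes: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Smooth bump of unit height and support ``center +/- halfwidth``."""
    u = (minutes - center) / halfwidth
    out = np.zeros_like(minutes, dtype=float)
    mask = np.abs(u) < 1
    out[mask] = 0.5 * (1.0 + np.cos(np.pi * u[mask]))
    return out


def _subject_days(config: CohortConfig, rng: np.random.Generator) -> int:
    if isinstance(config.days_per_subject, (tuple, list)):
        lo, hi = config.days_per_subject
        return int(rng.integers(lo, hi + 1))
    return int(config.days_per_subject)


def generate_subject(config: CohortConfig, subject_index: int
                     ) -> tuple[GlucoseSeries, list[SleepEpisode]]:
    """Generate one subject's glucose series and nightly sleep episodes.

    Fully deterministic given ``(config.seed, subject_index)``. The
    series holds exactly ``days * (1440 / sampling_minutes)`` readings
    starting at midnight of the first day; one main sleep episode is
    generated per night (the last night's sleep necessarily runs past
    the end of the recording).
    """
    config.validate()
    if subject_index < 0 or subject_index >= config.n_subjects:
        raise ConfigError("subject_index", "must be < n_subjects")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(subject_index)]))
    days = _subject_days(config, rng)
    per_day = 1440 // config.sampling_minutes
    n = days * per_day
    minutes = np.arange(n, dtype=float) * config.sampling_minutes
    times = BASE_DATE + pd.to_timedelta(minutes, unit="m")

    # --- sleep schedule: one main episode per night -------------------
    onset_hours = rng.normal(config.sleep_onset_hour_mean,
                             config.sleep_onset_hour_sd, days)
    durations = np.clip(rng.normal(config.sleep_duration_hours_mean,
                                   config.sleep_duration_hours_sd, days),
                        4.0, 11.0)
    onsets_min = np.empty(days)
    offsets_min = np.empty(days)
    for d in range(days):
        onset = d * 1440.0 + onset_hours[d] * 60.0
        if d > 0:
            onset = max(onset, offsets_min[d - 1] + 6 * 60.0)
        onsets_min[d] = onset
        offsets_min[d] = onset + durations[d] * 60.0

    subject_id = f"S{subject_index + 1:02d}"
    episodes = [SleepEpisode(subject_id,
                             BASE_DATE + pd.Timedelta(minutes=onsets_min[d]),
                             BASE_DATE + pd.Timedelta(minutes=offsets_min[d]))
                for d in range(days)]
    naps = []
    if config.nap_prob > 0:
        for d in range(days):
            if rng.random() < config.nap_prob:
                start = d * 1440.0 + rng.uniform(13.5, 15.0) * 60.0
                naps.append(SleepEpisode(
                    subject_id, BASE_DATE + pd.Timedelta(minutes=start),
                    BASE_DATE + pd.Timedelta(minutes=start + rng.uniform(30, 80))))

    # --- random structure drawn up-front for determinism --------------
    subject_offset = rng.normal(0.0, config.subject_sd_mgdl)
    u = rng.normal(0.0, config.awake_day_sd_mgdl, days)  # awake-day deviations
    w = rng.normal(0.0, 1.0, days)                       # sleep-day innovations
    dip_flag = rng.random(days) < config.hypo_dip_prob
    dip_frac = rng.uniform(0.15, 0.85, days)
    plant_draw = rng.random(days)
    meal_jitter = rng.uniform(-30.0, 30.0, (days, max(config.meal_count_per_day, 1)))
    meal_amp = rng.uniform(0.8, 1.2, (days, max(config.meal_count_per_day, 1)))
    innovations = rng.normal(0.0, 1.0, n)

    # stationary standardized AR(1) noise
    rho = config.ar_coefficient
    e = np.empty(n)
    scale = math.sqrt(1.0 - rho ** 2)
    e[0] = innovations[0]
    for k in range(1, n):
        e[k] = rho * e[k - 1] + scale * innovations[k]

    circadian = config.circadian_amplitude_mgdl * np.cos(
        2 * np.pi * ((minutes / 60.0) % 24.0 - 16.0) / 24.0)

    if config.meal_count_per_day == 3:
        meal_clock = np.array([8.0, 13.0, 19.0])
    else:
        meal_clock = np.linspace(7.5, 20.0, max(config.meal_count_per_day, 1))

    base = config.awake_mean_mgdl + subject_offset
    gamma = config.coupling_gamma
    values = np.empty(n)

    def fill_region(lo_min: float, hi_min: float, level: float,
                    shape: np.ndarray, sd: float) -> None:
        mask = (minutes >= lo_min) & (minutes < hi_min)
        if not mask.any():
            return
        centred = shape[mask] - shape[mask].mean()
        values[mask] = level + centred + sd * e[mask]

    for d in range(days):
        # awake window of day d: [previous offset, onset d)
        awake_lo = 0.0 if d == 0 else offsets_min[d - 1]
        awake_hi = onsets_min[d]
        meals = np.zeros(n)
        for m in range(config.meal_count_per_day):
            center = d * 1440.0 + meal_clock[m] * 60.0 + meal_jitter[d, m]
            meals += (config.meal_excursion_amplitude_mgdl * meal_amp[d, m]
                      * _raised_cosine(minutes, center,
                                       config.meal_halfwidth_minutes))
        fill_region(awake_lo, awake_hi, base + u[d], meals + circadian,
                    config.awake_sd_mgdl)

        # sleep window of night d: [onset d, offset d)
        if config.awake_day_sd_mgdl > 0:
            z = u[d] / config.awake_day_sd_mgdl
        else:
            z = 0.0
        v = config.sleep_day_sd_mgdl * (gamma * z
                                        + math.sqrt(1.0 - gamma ** 2) * w[d])
        sleep_level = base + config.sleep_mean_offset_mgdl + v
        shape = circadian.copy()
        if dip_flag[d]:
            span = offsets_min[d] - onsets_min[d] - 2 * config.hypo_dip_halfwidth_minutes
            center = (onsets_min[d] + config.hypo_dip_halfwidth_minutes
                      + dip_frac[d] * max(span, 0.0))
            target_min = (config.awake_mean_mgdl + config.sleep_mean_offset_mgdl
                          - config.hypo_dip_depth_mgdl)
            amp = sleep_level - target_min
            if amp > 0:
                shape = shape - amp * _raised_cosine(
                    minutes, center, config.hypo_dip_halfwidth_minutes)
        # the dip must depress the segment mean, so only the circadian
        # part of the shape is centred
        mask = (minutes >= onsets_min[d]) & (minutes < offsets_min[d])
        if mask.any():
            centred_circ = circadian[mask] - circadian[mask].mean()
            dip_part = shape[mask] - circadian[mask]
            values[mask] = (sleep_level + centred_circ + dip_part
                            + config.sleep_sd_mgdl * e[mask])
            night_vals = np.clip(values[mask], 40.0, 400.0)
            realized_min = np.rint(night_vals).min()
            if (config.planted_rule_strength > 0 and d + 1 < days
                    and realized_min < SEVERE_LOW_MGDL
                    and plant_draw[d] < config.planted_rule_strength):
                u[d + 1] = -config.planted_shift_mgdl

    values = np.rint(np.clip(values, 40.0, 400.0))
    series = GlucoseSeries(subject_id=subject_id, timestamps=pd.DatetimeIndex(times),
                           values=values,
                           sampling_minutes=config.sampling_minutes)
    all_eps = sorted(episodes + naps, key=lambda ep: ep.onset)
    return series, all_eps


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate all subjects; same config and seed give identical output."""
    config.validate()
    subjects = {}
    for idx in range(config.n_subjects):
        series, episodes = generate_subject(config, idx)
        subjects[series.subject_id] = (series, episodes)
    return Cohort(config=config, subjects=subjects)


def plant_rule_scenario(config: CohortConfig, strength: float) -> CohortConfig:
    """Return a config in which severe-low nights drive next-day low glucose.

    With probability ``strength``, an awake day following a night whose
    minimum fell below 54 mg/dl is shifted down by ``planted_shift_mgdl``
    so that its LBGI lands in the cohort's top tertile. Dip depth and
    frequency are raised if needed so that severe-low nights actually
    occur (target nocturnal minimum <= 50 mg/dl on dip nights).
    ``strength=0`` returns the config unchanged.
    """
    if not 0.0 <= strength <= 1.0:
        raise ConfigError("strength", "must lie in [0, 1]")
    if strength == 0:
        return config
    depth_needed = (config.awake_mean_mgdl + config.sleep_mean_offset_mgdl
                    - 50.0)
    return replace(
        config,
        planted_rule_strength=strength,
        hypo_dip_depth_mgdl=max(config.hypo_dip_depth_mgdl, depth_needed),
        hypo_dip_prob=max(config.hypo_dip_prob, 0.25),
    )
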