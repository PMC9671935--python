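import logging

import pytest

from gvarm import (CohortConfig, PipelineConfig, generate_cohort,
                   plant_rule_scenario, run, segment_days)
from gvarm.pipeline import profiles_from_segments

logging.getLogger("gvarm").setLevel(logging.ERROR)


def cohort_days(config):
    """Segment every subject of a generated cohort."""
    cohort = generate_cohort(config)
    days = []
    for sid in sorted(cohort.subjects):
        series, episodes = cohort.subjects[sid]
        days.extend(segment_days(series, episodes))
    return days


@pytest.fixture(scope="session")
def default_cohort_config():
    return CohortConfig(n_subjects=12, days_per_subject=14, seed=0)


@pytest.fixture(scope="session")
def default_days(default_cohort_config):
    return cohort_days(default_cohort_config)


@pytest.fixture(scope="session")
def default_profiles(default_days):
    return profiles_from_segments(default_days)


@pytest.fixture(scope="session")
def planted_report():
    """Full pipeline on a 12x14 cohort with the planted severe-low ->
    next-day-high-LBGI association at strength 1."""
    cfg = plant_rule_scenario(
        CohortConfig(n_subjects=12, days_per_subject=14, seed=1), 1.0)
    return run(PipelineConfig(cohort=cfg, seed=1))
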