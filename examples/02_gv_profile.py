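"""Segment one subject's series by recorded sleep and profile a day.

Shows the 12 glycemic variability metrics computed separately on the
in-sleep and awake segments of a single day. The target range for
tir/mge/mgn is the segment's own mean +/- sd, so it adapts to the
person's baseline.
"""

from gvarm import CohortConfig, generate_subject, profile, segment_days

series, episodes = generate_subject(
    CohortConfig(n_subjects=1, days_per_subject=7, seed=7), 0)
days = segment_days(series, episodes)
day = next(d for d in days if d.sleep_complete and d.awake_complete)

for role, segment in (("awake", day.awake), ("sleep", day.sleep)):
    p = profile(segment.to_numpy(), k=1.0, segment_role=role)
    print(f"{role} segment of {day.day_index} ({p.n} readings):")
    for name, value in p.metric_dict().items():
        print(f"  {name:>8s} = {value:8.2f}")
# Expect the sleep segment to sit lower (mean) and flatter (sd, cv)
# than the awake one; LBGI rises when readings drop below ~112.5 mg/dl,
# HBGI only when they exceed it.
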