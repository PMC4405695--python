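"""Vesicle motion statistics: confined vs. linear tracks, two conditions.

Simulates Rab6A-vesicle-like trajectories for a "control" and a
"motor-depleted" condition (the depleted condition has a wider
confinement zone and more frequent reversals), classifies every track
by its MSD exponent, and compares the per-track statistics between
conditions with the Wilcoxon rank-sum test.
"""

import numpy as np

from vesitrack import TrackSimParams, analyze_tracks, compare_groups, simulate_track


def simulate_condition(name, confinement_radius, reversal_rate, n_each, seed0):
    tracks = []
    for i in range(n_each):
        tracks.append(simulate_track(TrackSimParams(
            mode="confined", confinement_radius=confinement_radius,
            n_frames=200, seed=seed0 + i)))
        tracks.append(simulate_track(TrackSimParams(
            mode="directed", speed=0.5, reversal_rate=reversal_rate,
            pause_rate=0.1, n_frames=200, seed=seed0 + 1000 + i)))
    reports = analyze_tracks(tracks)
    print(f"{name}: {dict(reports['track_class'].value_counts())}")
    return reports


control = simulate_condition("control ", 0.3, 0.05, 60, seed0=0)
depleted = simulate_condition("depleted", 0.42, 0.09, 60, seed0=5000)

for metric in ("confinement_area", "mean_speed", "direction_changes_per_s",
               "pause_rate"):
    res = compare_groups(control, depleted, metric)
    print(f"{metric:>24}: {res.mean_a:.4f} -> {res.mean_b:.4f} "
          f"({res.fold_change:.2f}x, rank-sum p = {res.pvalue:.2e})")

print("""
Confinement area is the minimal enclosing circle of each confined
track (µm²); direction changes are principal-axis sign flips per
second in linear tracks, excluding pauses (< 0.1 µm/s).  The depleted
condition should show a larger confinement area and more reversals,
while pause rates stay similar — mirroring how the analysis separates
a motor's confinement and directionality roles from stalling.""")
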