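"""Partition the retained region into k-means segments and schedule points.

Each segment receives at least 3 Raman points and the ~15-minute budget
(at 3.5 s per spectrum) is shared among segments by area, so larger
segments are sampled more densely.
"""

from aframan import (
    ScreenLabel,
    demo_tissue_map,
    plan_sampling,
    ratiometric,
    render_af_pair,
    screen_adipose,
    segment,
)

tmap = demo_tissue_map(shape=(200, 200), tumour_radius_px=35, seed=1)
pair = render_af_pair(tmap, seed=1)
rimg = ratiometric(pair, tmap.specimen_mask)
retained = screen_adipose(rimg) == ScreenLabel.RETAINED

seg = segment(retained, target_segment_px=1000, seed=1)
plan = plan_sampling(seg, min_points=3, t_acq_s=3.5, budget_s=900.0, seed=1)

print(f"retained area: {int(retained.sum())} px -> K = {seg.K} segments")
counts = plan.placed_counts()
print(f"scheduled {len(plan.points)} points "
      f"({plan.total_time_s:.0f} s of {plan.budget_s:.0f} s budget)")
print("points per segment: min", min(counts.values()), "max", max(counts.values()))
print("budget exceeded:", plan.budget_exceeded)
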