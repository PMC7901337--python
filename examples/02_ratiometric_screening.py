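"""Screen adipose tissue out of a specimen with the ratiometric image.

Divides the two AF channels, applies the 0.2/0.8/2 multi-level
thresholds, and reports how much surface each ratio band occupies.  The
retained band (ratio 0.8-2) is what the Raman stage will sample; the
screening removes the adipose majority of the surface from consideration.
"""

import numpy as np

from aframan import (
    ScreenLabel,
    auto_mask_threshold,
    demo_tissue_map,
    mask_background,
    multilevel_threshold_report,
    ratiometric,
    render_af_pair,
    screen_adipose,
)

tmap = demo_tissue_map(shape=(200, 200), tumour_radius_px=35, seed=1)
pair = render_af_pair(tmap, seed=1)

threshold = auto_mask_threshold(pair.filter2)
mask = mask_background(pair.filter2, threshold)
rimg = ratiometric(pair, mask)
screen = screen_adipose(rimg)

print(f"mask threshold (automatic): {threshold:.0f} counts")
report = multilevel_threshold_report(rimg, [0.2, 0.8, 2.0])
for (lo, hi), frac in zip(report["intervals"], report["area_fractions"]):
    print(f"  ratio band {lo:.1f}-{hi:.1f}: {frac:.3f} of masked area")
n_mask = int(mask.sum())
print("screened out as adipose:", f"{(screen == ScreenLabel.ADIPOSE).sum() / n_mask:.3f}")
print("retained for Raman:     ", f"{(screen == ScreenLabel.RETAINED).sum() / n_mask:.3f}")
tumour_lost = int(((screen == ScreenLabel.ADIPOSE) & (tmap.labels == 3)).sum())
print("true tumour pixels screened out as adipose:", tumour_lost)
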