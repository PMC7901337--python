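"""Build a synthetic excision surface and render its two AF channels.

The demo specimen is an adipose field with a central tumour wrapped in a
stroma halo.  The printed band ratios are the per-class Filter1/Filter2
quotients the screening step relies on: adipose below 0.8, stroma and
tumour between 0.8 and 2.
"""

from aframan import class_band_ratios, demo_tissue_map, render_af_pair

tmap = demo_tissue_map(shape=(200, 200), tumour_radius_px=35, seed=1)
pair = render_af_pair(tmap, seed=1)

print("specimen pixels:", int(tmap.specimen_mask.sum()), "of", tmap.labels.size)
for name, frac in tmap.class_fractions().items():
    if frac:
        print(f"  {name:8s} {frac:.3f} of specimen")
print("noiseless Filter1/Filter2 band ratios:")
for name, ratio in class_band_ratios().items():
    print(f"  {name:8s} {ratio:.3f}")
print("rendered Filter2 peak counts:", int(pair.filter2.max()))
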