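"""Quantify the color composition and texture of a face stimulus.

Renders one synthetic stimulus with a known color composition, runs the
HSL-bin quantification on it, and shows that the recovered class
fractions equal the generating truth exactly (the renderer paints exact
integer pixel counts per class).
"""

from primatefaces import imagequant as iq
from primatefaces import synthdata as sd

panel = sd.generate_species_panel(2, seed=1)
spec = panel[-1]  # a catarrhine: red-brown dominated coat
img, truth = sd.render_stimulus(spec, width=96, height=128, seed=0)
profile = iq.color_profile(img)

print(f"species {spec.species_id} ({spec.group}), "
      f"{profile.n_opaque} opaque pixels")
print(f"{'class':>13} {'truth':>8} {'recovered':>10} {'arcsin-sqrt':>12}")
for cname in iq.COLOR_CLASSES:
    print(f"{cname:>13} {truth[cname]:8.4f} {profile.fractions[cname]:10.4f} "
          f"{profile.transformed_fractions[cname]:12.4f}")
print(f"mean lightness {profile.mean_lightness:.3f}, "
      f"mean saturation {profile.mean_saturation:.3f}, "
      f"pattern {profile.pattern:.3f} (generating level {spec.pattern_level:.3f})")
print("\nRecovered fractions are exact: the class-wise pixel counts are")
print("constructed, so any mismatch would indicate a classification bug.")
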