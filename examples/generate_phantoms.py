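"""Render phantom fundus images and inspect their ground truth.

Generates one glaucoma and one normal phantom, prints the geometry that
downstream stages must recover, and writes the images and vessel masks
as PNGs next to this script.
"""

from pathlib import Path

from fundustruct import generate_phantom, write_image

out = Path(__file__).parent / "output"
out.mkdir(exist_ok=True)

for label in ("glaucoma", "normal"):
    s = generate_phantom(label, seed=7)
    cdr = s.cup_radius / s.disc_radius
    print(f"{label:8s}: disc center {tuple(round(c, 1) for c in s.disc_center)}, "
          f"radius {s.disc_radius:.1f} px, cup-to-disc ratio {cdr:.2f}, "
          f"vessel pixels {int(s.vessel_mask.pixels.sum())}")
    write_image(s.image, out / f"phantom_{label}.png")
    write_image(s.vessel_mask, out / f"phantom_{label}_vessels.png")

print(f"\nimages written to {out}/")
print("The cup-to-disc ratio is the class signal: >= 0.7 for glaucoma, "
      "<= 0.4 for normal phantoms.")
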