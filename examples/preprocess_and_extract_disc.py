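"""Preprocess a phantom and localize its optic disc.

Runs the preprocessing chain (background mask, mean fill, CLAHE on the
CIELab L channel, background restore) and the Hough-based disc detector,
then compares the detected circle with the generator's ground truth.
"""

from fundustruct import generate_phantom, preprocess_fundus, extract_disc_region

sample = generate_phantom("glaucoma", seed=3)
enhanced, mask = preprocess_fundus(sample.image)
print(f"eye-region pixels: {int(mask.pixels.sum())} "
      f"({mask.pixels.mean():.1%} of the frame)")

crop = extract_disc_region(sample.image)
circle = crop.meta["disc_circle"]
true_row, true_col = sample.disc_center
print(f"detected disc ({circle.source}): center "
      f"({circle.center_row:.0f}, {circle.center_col:.0f}) in right-half "
      f"coordinates, radius {circle.detected_radius:.0f} px (+40 extension)")
print(f"ground truth:  center ({true_row:.0f}, {true_col - 256:.0f}), "
      f"radius {sample.disc_radius:.0f} px")
err_c = ((circle.center_row - true_row) ** 2
         + (circle.center_col - (true_col - 256)) ** 2) ** 0.5
print(f"center error {err_c:.1f} px, radius error "
      f"{abs(circle.detected_radius - sample.disc_radius):.1f} px")
print(f"disc crop for the classifier: {crop.pixels.shape} gray image")
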