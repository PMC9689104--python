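"""Generate a small cohort of synthetic carotid-ultrasound phantoms and
summarize their geometry.

Each phantom is an image/plaque-mask/vessel-mask triplet: a dark lumen
band between bright wall layers, plaques bulging into the lumen,
multiplicative speckle, and occasional shadows/streaks.  The printed
numbers are pixel counts: every plaque lies strictly inside the vessel.
"""

import numpy as np

from hrunet import PhantomParams, generate_dataset

params = PhantomParams(seed=7)           # 128 x 128 desk-scale default
samples = generate_dataset(8, params)

print(f"{'idx':>3} {'plaque px':>10} {'vessel px':>10} {'inside vessel':>14}")
for i, s in enumerate(samples):
    inside = not np.any(s.plaque_mask.astype(bool) & ~s.vessel_mask.astype(bool))
    print(f"{i:>3} {int(s.plaque_mask.sum()):>10} "
          f"{int(s.vessel_mask.sum()):>10} {str(inside):>14}")

img = samples[0].image
print(f"\nimage intensity range: [{img.min():.3f}, {img.max():.3f}] "
      "(valid ultrasound display range [0, 1])")
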