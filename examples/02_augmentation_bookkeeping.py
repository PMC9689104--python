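"""Training-pool construction: six-transform general augmentation plus
two cropped-blood-vessel (CBV) variants per original image.

With N originals the pool holds 8N pairs — 6N geometric variants plus
2N CBV images (the image multiplied by its vessel mask and the vertical
flip of that product).  The provenance counts printed below reproduce
the training-cohort arithmetic: 40 originals -> 320 pairs, and a
36-image cross-validation training split -> 288 pairs.
"""

from collections import Counter

from hrunet import PhantomParams, build_training_set, generate_dataset

params = PhantomParams(seed=1).scaled_to(32, 32)

for n in (40, 36, 1):
    pool = build_training_set(generate_dataset(n, params))
    tags = Counter(p.provenance for p in pool)
    print(f"{n:>3} originals -> {len(pool):>3} training pairs "
          f"({dict(sorted(tags.items()))})")
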