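"""Anatomy of the segmentation network: encoder pyramid, channel
reduction, HAC placement, softmax output.

The encoder is a ResNet-50 trunk; each block's output is compressed by
a 1x1 convolution (64->32, 256->64, 512->96, 1024->128, 2048->128)
before entering the skip connections, and HAC modules enrich the three
deepest levels.  The printed shapes show the H/2 ... H/32 pyramid and
the full-resolution two-class probability map.
"""

import numpy as np

from hrunet import ModelConfig, build_hrunet

config = ModelConfig(in_height=64, in_width=64, seed=0)
model = build_hrunet(config)
print(f"parameters: {model.n_parameters():,}")
print(f"HAC modules at: {config.hac_placement}")

x = np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)
raw = model.encoder(x)
pyramid = model.encoder_features(x)
print(f"\n{'stage':<11} {'raw shape':<20} {'reduced shape'}")
for name in ("conv_block", "res1", "res2", "res3", "res4"):
    print(f"{name:<11} {str(raw[name].shape):<20} "
          f"{getattr(pyramid, name).shape}")

prob = model.predict_proba(x)
print(f"\noutput ProbMap: {prob.shape}, per-pixel sums in "
      f"[{prob.sum(axis=1).min():.6f}, {prob.sum(axis=1).max():.6f}]")
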