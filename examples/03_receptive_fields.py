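"""Receptive-field arithmetic of dilated (atrous) convolutions.

A stride-1 stack of convolutions sees RF = 1 + sum(r * (K - 1)) input
pixels per output pixel.  The HAC module's cascaded chain of 3x3 convs
at rates 1, 2, 3 therefore covers a 13 x 13 window — verified here both
by the closed form and by pushing a single-pixel impulse through a real
convolution cascade and measuring the nonzero extent of the response.
"""

import numpy as np

from hrunet import receptive_field
from hrunet.nn import Conv2d


def impulse_extent(rates, n=64):
    x = np.zeros((1, 1, n, n), dtype=np.float32)
    x[0, 0, n // 2, n // 2] = 1.0
    for r in rates:
        conv = Conv2d(1, 1, 3, dilation=r)
        conv.weight.value[...] = 1.0
        x = conv.forward(x)
    nz = np.argwhere(x[0, 0] != 0)
    return int(nz[:, 0].max() - nz[:, 0].min() + 1)


for rates in ([1], [2], [1, 2], [1, 2, 3]):
    rf = receptive_field([3] * len(rates), rates)
    measured = impulse_extent(rates)
    print(f"3x3 convs at rates {rates}: closed-form RF {rf:>2}, "
          f"impulse-measured {measured:>2}")
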