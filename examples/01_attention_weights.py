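"""Inspect the Eca-CBAM attention weights on a toy feature map.

Builds a random (1, 8, 6, 6) activation tensor, applies ECA channel
attention and CBAM-style spatial attention, and prints the learned-shape
weights.  Channel weights (one per channel) and the spatial map (one per
pixel) both lie strictly in (0, 1): attention re-scales, never amplifies.
"""

import numpy as np

from hahnet.attention import eca_channel_attention, eca_kernel_size, spatial_attention

rng = np.random.default_rng(0)
x = rng.normal(size=(1, 8, 6, 6))

k = eca_kernel_size(channels=8)
print(f"adaptive ECA kernel size for C=8: k={k}")

omega, x_channel = eca_channel_attention(x, rng.normal(size=k) * 0.5)
print("channel weights omega:", np.round(omega[0], 3))

ms, x_both = spatial_attention(x_channel, rng.normal(size=(1, 2, 7, 7)) * 0.2)
print("spatial map Ms (first row):", np.round(ms[0, 0], 3))
print("max |output| / |input| ratio:", float(np.max(np.abs(x_both) / (np.abs(x) + 1e-12))))
# the ratio is < 1: both attention stages only attenuate
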