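"""Walk a feature map through the dense/multiscale/attention blocks.

Shapes follow the block algebra: a dense block adds N*g channels, a
transition halves the spatial size, the multiscale block concatenates
its four branch widths, and the attention blocks preserve shape while
rescaling (gates in (0,1)) or mixing spatial positions.
"""

import numpy as np

from btc.features import (
    AttentionConfig,
    DenseBlockConfig,
    aggregate_attention,
    channel_attention,
    dense_block,
    multiscale_extract,
    self_attention,
    spatial_attention,
    transition,
)

rng = np.random.default_rng(0)
x = rng.random((16, 16, 8))
print(f"input                {x.shape}")

x = dense_block(x, DenseBlockConfig(stages=2, growth_rate=4,
                                    initial_channels=8), seed=1)
print(f"dense block (N=2,g=4) -> {x.shape}   (8 + 2*4 = 16 channels)")

x = transition(x, seed=2)
print(f"transition            -> {x.shape}   (1x1 conv + 2x2 avg pool)")

x = multiscale_extract(x, branch_widths=(8, 8, 8, 8), seed=3)
print(f"multiscale            -> {x.shape}   (4 branches concatenated)")

cfg = AttentionConfig(heads=4)
f_sab = self_attention(x, cfg, seed=4)
f_sb = spatial_attention(x, seed=5)
agg = aggregate_attention(f_sab, f_sb)
out = channel_attention(agg, cfg, seed=6)
print(f"self+spatial+channel  -> {out.shape}   (shape preserved)")
print(f"feature vector (GAP)  -> {out.mean(axis=(0, 1)).shape}")
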