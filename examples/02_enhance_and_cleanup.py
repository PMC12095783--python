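"""Denoise a phantom with the AGSW guided filter and strip non-brain
structures morphologically.

The filter fits a local linear model of a gradient-derived guidance
image under anisotropic Gaussian side-window weights; flat regions are
smoothed while the side-window selection keeps lesion and brain edges
sharp.  The cleanup thresholds, opens, fills and keeps the largest
connected component.
"""

import numpy as np

from btc.enhance import AGSWParams, agsw_filter, morphological_cleanup
from btc.phantom import PhantomSpec, generate_phantom

img = generate_phantom(PhantomSpec(64, "glioma", noise_sd=0.05, seed=3))
z, coeffs = agsw_filter(img.pixels, AGSWParams())
mask, masked = morphological_cleanup(np.clip(z, 0, 1))

from scipy.ndimage import binary_dilation, binary_erosion

inside = img.pixels > 0.15
flat = binary_erosion(inside, iterations=3) & ~binary_dilation(img.mask,
                                                               iterations=3)
print(f"noise variance (flat brain): raw {img.pixels[flat].var():.4f} "
      f"-> filtered {z[flat].var():.4f}")
print(f"lesion/brain contrast: raw "
      f"{img.pixels[img.mask].mean() - img.pixels[flat].mean():.3f} "
      f"-> filtered {z[img.mask].mean() - z[flat].mean():.3f}")
print(f"brain mask keeps {mask.mean():.0%} of pixels "
      f"(ground-truth lesion fully inside: {bool((mask & img.mask).sum() == img.mask.sum())})")

# Variance drops in flat tissue while the lesion contrast survives —
# that is the edge-preserving property the side windows buy.
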