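"""Reproduce the frozen global H/DAB thresholds from calibration cores.

Five synthetic cores provide the mean RGB of stained nuclei and of the
bright background.  Because pixel blending happens in transmittance
while deconvolution works in log space, the channel value of a pixel
exactly half covered by stain is not the midpoint of the stained and
background channel levels; each default threshold is that
half-coverage value, so a pixel counts as positive once stain covers
at least half of it.  This keeps measured areas unbiased when images
are box-downscaled.
"""

import numpy as np

from slidequant.ihc import DEFAULT_THRESHOLDS, color_deconvolve
from slidequant.synthetic import IhcSceneParams, generate_ihc_core

hem_rgb, pos_rgb, bg_rgb = [], [], []
for s in range(5):
    image, truth = generate_ihc_core(IhcSceneParams(seed=1000 + s,
                                                    positive_fraction=0.3))
    hem_only = truth.nucleus_mask & ~truth.positive_mask
    hem_rgb.append(image[hem_only].mean(axis=0))
    pos_rgb.append(image[truth.positive_mask].mean(axis=0))
    bg_rgb.append(image[~truth.nucleus_mask].mean(axis=0))


def half_coverage(stained, background, channel):
    """Deconvolved channel value of a half-stained, half-background pixel."""
    blend = np.clip(np.round(0.5 * stained + 0.5 * background),
                    0, 255).astype(np.uint8).reshape(1, 1, 3)
    ch = color_deconvolve(blend)
    raster = ch.h_channel if channel == "h" else ch.dab_channel
    return int(raster[0, 0])


bg = np.mean(bg_rgb, axis=0)
h_half = half_coverage(np.mean(hem_rgb, axis=0), bg, "h")
dab_half = half_coverage(np.mean(pos_rgb, axis=0), bg, "dab")
print(f"half-covered haematoxylin nucleus -> H channel  {h_half}")
print(f"half-covered DAB-positive nucleus -> DAB channel {dab_half}")
print(f"frozen defaults: h={DEFAULT_THRESHOLDS.h_threshold} "
      f"dab={DEFAULT_THRESHOLDS.dab_threshold}")
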