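"""Score a synthetic IHC core and compare with its planted ground truth.

The extent of staining is the DAB-positive area divided by the union of
haematoxylin- and DAB-positive areas; on a synthetic core the planted
positive-pixel fraction is known exactly, so the printed difference is
the scorer's error.
"""

from slidequant.ihc import quantify
from slidequant.synthetic import IhcSceneParams, generate_ihc_core

params = IhcSceneParams(positive_fraction=0.35, seed=42)
image, truth = generate_ihc_core(params)
result = quantify(image)

print(f"planted extent      : {truth.true_extent:.4f}")
print(f"measured extent     : {result.extent:.4f}")
print(f"mean DAB intensity  : {result.intensity_pct:.1f}%")
print(f"pixels  DAB/H-only/background: {result.n_dab_pixels} / "
      f"{result.n_h_only_pixels} / {result.n_background_pixels}")
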