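"""Stored file size per compression × scaling condition.

Encodes one synthetic core under every condition of a reduced grid and
prints the stored bytes — the archival cost of each setting.  Sizes
fall steeply along both axes until the JPEG2000 header floor
(~0.3 KB) dominates.
"""

from slidequant.experiment import GridSpec, file_size_table
from slidequant.synthetic import IhcSceneParams, generate_ihc_core

image, _ = generate_ihc_core(IhcSceneParams(seed=1))
grid = GridSpec(compression_ratios=(None, 12, 25, 50),
                scaling_factors=(1, 2, 4, 8))
sizes = file_size_table(image, grid)

print(f"raw RGB payload: {image.size} bytes")
print("\nstored bytes:")
print(sizes.astype(int).to_string())
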