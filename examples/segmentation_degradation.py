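"""Segmentation agreement across JPEG2000 compression ratios.

Classifies held-out annotations after compression at 1:12, 1:25 and
1:50 and compares predictions to the lossless reference.  Agreement
declines gently to 1:25 and drops sharply at 1:50, where compression
erases the fine texture the classifier relies on.  No scaling series is
run: the LBP operator is scale-variant.
"""

from slidequant.experiment import run_seg_series
from slidequant.segmentation import fit_segmenter
from slidequant.synthetic import generate_texture_image, texture_params

train = [generate_texture_image(p)
         for p in texture_params(20, base_seed=300, mix_range=(0.0, 0.0))]
model, quantizers = fit_segmenter([im for im, _ in train],
                                  [lab for _, lab in train])

test = [generate_texture_image(p)[0]
        for p in texture_params(20, base_seed=301)]
report = run_seg_series(test, model, quantizers)

table = report.agreement.join(report.kappa)
print(table.round(4).to_string())
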