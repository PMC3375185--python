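"""Train the epithelium/stroma classifier and score unseen annotations.

A linear C-SVM (C=300) on 224-bin LBP+VAR element histograms is trained
on texture-pure synthetic annotations; mean element decision values
classify held-out images (positive = epithelium), with |score| <= 1
flagged as a weak call.
"""

from slidequant.segmentation import classify_image, fit_segmenter
from slidequant.synthetic import generate_texture_image, texture_params

train = [generate_texture_image(p)
         for p in texture_params(16, base_seed=100, mix_range=(0.0, 0.0))]
model, quantizers = fit_segmenter([im for im, _ in train],
                                  [lab for _, lab in train])

test = [generate_texture_image(p)
        for p in texture_params(4, base_seed=900, mix_range=(0.0, 0.2))]
print("true class   predicted    mean score  band   elements")
for image, label in test:
    r = classify_image(image, model, quantizers)
    print(f"{label:12s} {r.predicted_class:12s} {r.mean_score:+8.2f}   "
          f"{r.band:6s} {r.n_elements:4d}")
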