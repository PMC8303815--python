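"""Extract the 62-feature vector of one lesion and read a few entries.

Regions: lesion L, boundary lane LB (5 px either side of the contour),
dermis-under-lesion D.  Indices follow the frozen feature map
(1-20 first-order + shape, 21-62 GLCM blocks).
"""

from sonoskin import (FEATURE_NAMES, PhantomSpec, SkinLayers, derive_regions,
                      extract_features, generate_phantom, preprocess)

for label in ("nevus", "BCC", "MM"):
    s = generate_phantom(PhantomSpec(), label, seed=4)
    img = preprocess(s.image)
    regions = derive_regions(img, s.truth_mask, SkinLayers(*s.truth_layers))
    fv = extract_features(img, regions)
    print(f"{label}:")
    for idx in (2, 5, 8, 18, 29):
        print(f"  idx {idx:2d} {FEATURE_NAMES[idx - 1]:28s} {fv[idx]: .4f}")

# idx 2 (attenuation contrast) is the posterior-shadow strength: near 0 for
# nevi, clearly positive for BCCs.  idx 29 (vertical GLCM contrast of the
# lesion) responds to echotexture heterogeneity, though across classes it is
# confounded by echogenicity because gray levels are quantized over each
# region's own intensity range.
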