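"""How a few pixels of segmentation error can flip a classification.

A nevus phantom gets a hyperechoic patch along the inside of its right
border; the trained classifier calls it cancerous.  Shrinking the mask at
the right edge by a few pixels excludes the patch and flips the call back.
"""

import numpy as np

from sonoskin import (FEATURE_NAMES, PhantomSpec, SkinLayers, TaskSpec,
                      border_sensitivity, feature_table, generate_dataset,
                      generate_phantom, plant_hyperechoic_patch, preprocess,
                      stratified_folds, task_labeling, train_svm)

spec = PhantomSpec()
ds = generate_dataset(spec, (15, 15, 15), seed=9)
imgs = [preprocess(s.image) for s in ds.samples]
masks = [s.truth_mask for s in ds.samples]
lays = [SkinLayers(*s.truth_layers) for s in ds.samples]
table = feature_table(imgs, masks, lays, labels=ds.labels)
X = table[list(FEATURE_NAMES)].to_numpy(float)
sel, y = task_labeling(np.array(ds.labels),
                       TaskSpec("Nevus vs. others", "binary"))
model = train_svm(X[sel], y)

target = plant_hyperechoic_patch(generate_phantom(spec, "nevus", 424242))
grid = border_sensitivity(preprocess(target.image), target.truth_mask, model,
                          SkinLayers(*target.truth_layers), true_label=1,
                          amounts=(-4, -3, -2, -1, 0, 1, 2))

print("amounts:", grid.amounts, "(negative = shrink)")
for edge, row in zip(grid.edges, grid.predictions):
    cells = " ".join("nevus" if p == 1 else "other" for p in row)
    print(f"  {edge:13s} {cells}")
print("unperturbed prediction:",
      "nevus" if grid.reference_prediction == 1 else "other (fooled by patch)")

# Only the right-edge (and all-border) shrinks remove the planted patch, so
# only those rows flip back to the correct 'nevus' call.
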