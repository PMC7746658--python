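"""Apply the classic augmentation stack (rotation, shifts, zoom, flips).

Shows that augmentation preserves labels and batch size while producing
fresh images per epoch seed — the property the per-epoch training protocol
relies on.
"""

import numpy as np

from leafgan import (AugmentConfig, LeafDatasetSpec, augment_batch,
                     generate_dataset)

train, _ = generate_dataset(LeafDatasetSpec(
    n_classes=2, n_per_class_train=10, n_per_class_test=1, image_size=32,
    feature_strength=1.0, seed=0))

cfg = AugmentConfig(rotation_range=360, width_shift_range=0.3,
                    height_shift_range=0.3, zoom_range=0.3,
                    horizontal_flip=True, vertical_flip=True, seed=0)

epoch0 = augment_batch(train, cfg, epoch_seed=0)
epoch1 = augment_batch(train, cfg, epoch_seed=1)

print("labels preserved:", np.array_equal(epoch0.labels, train.labels))
print("batch size preserved:", len(epoch0) == len(train))
print("epochs differ:", not np.array_equal(epoch0.images, epoch1.images))
frac = np.mean(epoch0.images != train.images)
print(f"fraction of pixels changed by augmentation: {frac:.2f}")
# Labels and cardinality never change; different epoch seeds give different
# transforms, so each training epoch sees a fresh view of the same images.
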