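"""Published full-scale benchmark values for the four training regimes.

These are the reference results of the originating PlantVillage study (38
leaf classes, 873 training / 4,384 test images, GPU-scale training): the
training/test accuracies of the four regimes, and the per-class recall /
precision / F1 tables for the 26 diseased and 12 healthy class groups.
They serve as *inputs* for metric-reproduction checks — recomputing every
printed F1 cell and macro average from the printed recall/precision pairs —
and as orientation for users; nothing in this package re-derives them from
images (that would need the full dataset and GPU budgets).

Regime order everywhere: Experiment I (real images only), II (classic
augmentation), III (augmentation + WGAN-GP synthesis), IV (augmentation +
WGAN-GP-LSR synthesis).  Per-class arrays have shape (n_rows, 4, 3) with
the last axis ordered (recall, precision, F1) as printed, at two decimals.
"""

from __future__ import annotations

import numpy as np

__all__ = ["REGIMES", "ACCURACY_TABLE", "DISEASED_TABLE", "DISEASED_ROWS",
           "HEALTHY_TABLE", "HEALTHY_ROWS", "GENERATOR_TABLE",
           "DISCRIMINATOR_TABLE", "CLASSIFIER_TABLE",
           "EPOCH_COMPOSITION_TABLE", "TRAIN_COUNTS_38"]

REGIMES = ("I", "II", "III", "IV")

#: training / test accuracy (percent) per regime
ACCURACY_TABLE = {
    "I": {"train": 100.00, "test": 60.40},
    "II": {"train": 90.08, "test": 80.57},
    "III": {"train": 98.23, "test": 82.41},
    "IV": {"train": 97.84, "test": 84.78},
}

#: per-epoch data composition per regime:
#: (original, classic-augmented, synthetic-per-class × classes)
EPOCH_COMPOSITION_TABLE = {
    "I": (873, 0, 0),
    "II": (0, 873, 0),
    "III": (0, 873, 30 * 38),
    "IV": (0, 873, 30 * 38),
}

#: published per-class training-image counts of the 38-class limited set
#: (10-28 per class, 873 in total), in the class order of the source table
TRAIN_COUNTS_38 = (
    10, 13, 15, 20,          # Apple: three diseases + healthy
    22,                      # Blueberry healthy
    19, 14,                  # Cherry: disease + healthy
    27, 25, 24, 27,          # Corn: three diseases + healthy
    28, 21, 26, 26,          # Grape: three diseases + healthy
    28,                      # Orange disease
    27, 24,                  # Peach: disease + healthy
    16, 22,                  # Pepper: disease + healthy
    16, 24, 22,              # Potato: two diseases + healthy
    28,                      # Squash disease
    25, 28,                  # Strawberry: disease + healthy
    19,                      # Raspberry healthy
    28,                      # Soybean healthy
    27, 25, 28, 24, 28, 27, 21, 20, 25,  # Tomato: nine diseases
    24,                      # Tomato healthy
)

DISEASED_ROWS = [str(i) for i in range(1, 27)]

# rows: disease classes 1-26; columns: regimes I-IV; last axis (R, P, F)
DISEASED_TABLE = np.array([
    [[0.17, 0.89, 0.29], [0.48, 0.54, 0.51], [0.33, 0.88, 0.48], [0.46, 0.60, 0.52]],
    [[0.59, 0.61, 0.60], [0.86, 0.77, 0.81], [0.66, 0.84, 0.74], [0.93, 0.72, 0.81]],
    [[0.37, 0.41, 0.39], [0.50, 0.88, 0.64], [0.70, 0.75, 0.72], [0.30, 0.56, 0.39]],
    [[0.41, 0.85, 0.55], [0.88, 0.43, 0.58], [0.43, 0.93, 0.59], [0.71, 0.96, 0.82]],
    [[0.50, 0.42, 0.46], [0.69, 0.56, 0.62], [0.47, 0.68, 0.56], [0.56, 0.72, 0.63]],
    [[0.53, 0.80, 0.64], [0.89, 0.90, 0.89], [0.96, 0.73, 0.83], [0.92, 0.86, 0.89]],
    [[0.87, 0.65, 0.75], [0.78, 0.76, 0.77], [0.61, 0.91, 0.73], [0.81, 0.79, 0.80]],
    [[0.28, 0.40, 0.33], [0.94, 0.45, 0.61], [0.69, 0.87, 0.77], [0.74, 0.69, 0.71]],
    [[0.92, 0.55, 0.69], [0.67, 0.85, 0.75], [0.91, 0.91, 0.91], [0.91, 0.91, 0.91]],
    [[0.51, 0.84, 0.63], [0.62, 0.95, 0.75], [0.58, 0.91, 0.71], [0.60, 0.98, 0.74]],
    [[0.96, 0.66, 0.78], [0.93, 0.98, 0.95], [0.96, 0.95, 0.96], [0.99, 0.97, 0.98]],
    [[0.66, 0.93, 0.77], [0.95, 0.64, 0.77], [0.90, 0.90, 0.90], [0.95, 0.80, 0.87]],
    [[0.73, 0.43, 0.54], [0.85, 0.55, 0.67], [0.81, 0.71, 0.76], [0.93, 0.53, 0.68]],
    [[0.52, 0.75, 0.61], [0.84, 0.65, 0.74], [0.35, 0.93, 0.50], [0.89, 0.94, 0.91]],
    [[0.12, 0.78, 0.21], [0.79, 0.54, 0.64], [0.72, 0.95, 0.82], [0.69, 0.89, 0.78]],
    [[0.57, 0.98, 0.72], [0.94, 0.88, 0.91], [0.94, 0.82, 0.88], [0.86, 0.97, 0.91]],
    [[0.88, 0.78, 0.83], [0.71, 0.63, 0.67], [0.86, 0.84, 0.85], [0.89, 0.75, 0.82]],
    [[0.28, 0.62, 0.38], [0.62, 0.86, 0.72], [0.84, 0.79, 0.81], [0.66, 0.98, 0.79]],
    [[0.22, 0.65, 0.32], [0.53, 0.52, 0.52], [0.76, 0.57, 0.65], [0.62, 0.66, 0.64]],
    [[0.43, 0.59, 0.50], [0.62, 0.73, 0.67], [0.67, 0.77, 0.72], [0.70, 0.75, 0.73]],
    [[0.29, 0.54, 0.37], [0.54, 0.78, 0.64], [0.81, 0.92, 0.86], [0.81, 0.70, 0.75]],
    [[0.65, 0.57, 0.61], [0.52, 0.89, 0.66], [0.94, 0.52, 0.67], [0.76, 0.70, 0.73]],
    [[0.54, 0.67, 0.60], [0.63, 0.82, 0.71], [0.58, 0.97, 0.73], [0.72, 0.92, 0.81]],
    [[0.60, 0.45, 0.52], [0.31, 0.73, 0.44], [0.93, 0.53, 0.67], [0.81, 0.67, 0.73]],
    [[0.95, 0.74, 0.83], [0.89, 0.98, 0.94], [0.97, 0.89, 0.92], [0.99, 0.97, 0.98]],
    [[0.88, 0.62, 0.73], [0.92, 1.00, 0.96], [0.85, 0.92, 0.88], [0.92, 0.80, 0.86]],
])

HEALTHY_ROWS = ["Apple", "Blueberry", "Cherry", "Corn", "Grape", "Peach",
                "Pepper", "Potato", "Raspberry", "Soybean", "Strawberry",
                "Tomato"]

HEALTHY_TABLE = np.array([
    [[0.37, 0.72, 0.49], [0.93, 1.00, 0.96], [0.81, 0.92, 0.86], [0.89, 0.94, 0.91]],
    [[0.44, 0.74, 0.55], [0.91, 1.00, 0.95], [0.76, 0.97, 0.85], [0.84, 0.80, 0.82]],
    [[0.74, 0.35, 0.48], [0.88, 0.97, 0.92], [0.97, 0.71, 0.82], [0.92, 0.84, 0.88]],
    [[0.67, 0.72, 0.69], [1.00, 0.97, 0.98], [0.99, 0.89, 0.94], [0.91, 1.00, 0.95]],
    [[0.65, 0.50, 0.57], [0.74, 0.93, 0.82], [0.81, 0.62, 0.70], [0.77, 0.71, 0.74]],
    [[0.42, 0.55, 0.48], [0.96, 0.71, 0.82], [0.88, 0.82, 0.85], [0.65, 0.94, 0.77]],
    [[0.73, 0.17, 0.28], [0.79, 0.83, 0.81], [0.86, 0.68, 0.76], [0.94, 0.80, 0.86]],
    [[0.13, 0.22, 0.16], [0.13, 0.67, 0.22], [0.40, 1.00, 0.57], [0.53, 0.47, 0.50]],
    [[0.37, 0.76, 0.50], [0.90, 0.68, 0.77], [0.27, 1.00, 0.43], [0.80, 0.85, 0.82]],
    [[0.44, 0.77, 0.56], [0.98, 0.99, 0.98], [0.94, 0.92, 0.93], [0.92, 0.86, 0.89]],
    [[0.15, 0.38, 0.22], [0.53, 0.78, 0.63], [0.80, 0.71, 0.75], [0.60, 0.80, 0.69]],
    [[0.54, 0.70, 0.61], [0.85, 0.92, 0.88], [0.86, 0.97, 0.91], [0.86, 0.97, 0.91]],
])

# published architecture tables: (row label, output size) in order.
GENERATOR_TABLE = [
    ("Dense", (8, 8, 128)),
    ("Up sampling", (16, 16, 128)),
    ("Conv3-128", (16, 16, 128)),
    ("Up sampling", (32, 32, 128)),
    ("Conv3-64", (32, 32, 64)),
    ("Up sampling", (64, 64, 64)),
    ("Conv3-32", (64, 64, 32)),
    ("Up sampling", (128, 128, 32)),
    ("Conv3-3", (128, 128, 3)),
]

DISCRIMINATOR_TABLE = [
    ("Conv3-16(stride size = 2)", (64, 64, 16)),
    ("Conv3-32(stride size = 2)", (32, 32, 32)),
    ("Zero padding", (33, 33, 32)),
    ("Conv3-64(stride size = 2)", (17, 17, 64)),
    ("Conv3-128", (17, 17, 128)),
    ("Dense", (1,)),
    ("Dense", (38,)),
]

CLASSIFIER_TABLE = [
    ("Conv3-64", (128, 128, 64)),
    ("Conv3-64", (128, 128, 64)),
    ("MaxPooling", (64, 64, 64)),
    ("Conv3-128", (64, 64, 128)),
    ("Conv3-128", (64, 64, 128)),
    ("MaxPooling", (32, 32, 128)),
    ("Conv3-256", (32, 32, 256)),
    ("Conv3-256", (32, 32, 256)),
    ("Conv3-256", (32, 32, 256)),
    ("MaxPooling", (16, 16, 256)),
    ("Conv3-512", (16, 16, 512)),
    ("Conv3-512", (16, 16, 512)),
    ("Conv3-512", (16, 16, 512)),
    ("MaxPooling", (8, 8, 512)),
    ("Conv3-512", (8, 8, 512)),
    ("Conv3-512", (8, 8, 512)),
    ("Conv3-512", (8, 8, 512)),
    ("MaxPooling", (4, 4, 512)),
    ("AverPooling", (1, 1, 512)),
    ("Dense", (512,)),
    ("Dense", (38,)),
]
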