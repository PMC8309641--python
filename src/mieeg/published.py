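"""Published benchmark results for the IS-CBAM-CNN framework.

These are the per-subject accuracies (%, mean +- std over 10x10-fold
cross-validation) and kappa coefficients reported in the literature for
two-class motor imagery on BCI Competition IV dataset 2b (nine subjects) and
BCI Competition II dataset III (one subject), for the IS-CBAM-CNN method and
the competitor methods it was compared against.

They are *inputs* to the table-aggregation utilities — the package renders
and summarises them, it never recomputes competitor numbers.
"""

from __future__ import annotations

import numpy as np

SUBJECTS = tuple(range(1, 10))

#: BCI Competition IV dataset 2b accuracies (%).  ``std`` is None where the
#: source reported no dispersion.
ACCURACY_2B: dict[str, dict[str, np.ndarray | None]] = {
    "CapsNet": {
        "mean": np.array([78.8, 55.7, 55.0, 95.9, 83.1, 83.4, 75.6, 91.2, 87.1]),
        "std": None,
    },
    "BP-SVM": {
        "mean": np.array([65.4, 58.5, 64.4, 92.7, 77.1, 71.4, 68.4, 68.8, 65.9]),
        "std": np.array([4.7, 4.3, 5.9, 4.6, 6.6, 6.8, 7.6, 5.9, 6.1]),
    },
    "CNN-SAE": {
        "mean": np.array([76.0, 65.8, 75.3, 95.3, 83.0, 79.5, 74.5, 75.3, 73.3]),
        "std": np.array([2.7, 1.9, 1.8, 0.4, 1.4, 2.5, 1.8, 2.6, 3.6]),
    },
    "IS-CBAM-CNN": {
        "mean": np.array([80.3, 75.0, 67.7, 95.4, 88.3, 80.0, 73.7, 77.4, 78.6]),
        "std": np.array([1.5, 1.8, 2.6, 0.6, 1.5, 1.7, 2.2, 2.0, 2.1]),
    },
}

#: BCI Competition IV dataset 2b kappa coefficients (dimensionless).
KAPPA_2B: dict[str, dict[str, np.ndarray | None]] = {
    "Twin-SVM": {
        "mean": np.array(
            [0.494, 0.416, 0.322, 0.897, 0.722, 0.405, 0.466, 0.477, 0.503]
        ),
        "std": None,
    },
    "FBCSP": {
        "mean": np.array(
            [0.546, 0.208, 0.244, 0.888, 0.692, 0.534, 0.409, 0.413, 0.583]
        ),
        "std": np.array(
            [0.017, 0.028, 0.023, 0.003, 0.005, 0.012, 0.013, 0.013, 0.010]
        ),
    },
    "CNN-SAE": {
        "mean": np.array(
            [0.517, 0.324, 0.494, 0.905, 0.655, 0.579, 0.488, 0.494, 0.463]
        ),
        "std": np.array(
            [0.095, 0.065, 0.084, 0.017, 0.060, 0.099, 0.065, 0.106, 0.152]
        ),
    },
    "IS-CBAM-CNN": {
        "mean": np.array(
            [0.606, 0.500, 0.354, 0.908, 0.766, 0.600, 0.474, 0.548, 0.572]
        ),
        "std": np.array(
            [0.030, 0.036, 0.052, 0.012, 0.030, 0.034, 0.044, 0.040, 0.042]
        ),
    },
}

#: BCI Competition II dataset III, single subject: accuracy (%) and kappa.
DATASET_III: dict[str, dict[str, float]] = {
    "competition winner": {"accuracy": 89.3, "kappa": 0.783},
    "deep network": {"accuracy": 88.2, "kappa": 0.764},
    "CNN-SAE": {"accuracy": 90.0, "kappa": 0.800},
    "IS-CBAM-CNN": {"accuracy": 90.7, "kappa": 0.814},
}
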