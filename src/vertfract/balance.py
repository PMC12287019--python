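"""Class balancing: SMOTE in feature space and small-angle rotation
augmentation in image space.

SMOTE synthesizes minority-class samples by linear interpolation between a
minority sample and one of its k nearest minority neighbors (Euclidean),
x_new = x + u (x_n - x) with u ~ Uniform(0, 1).  Original rows are never
altered or relabeled; synthetic rows carry a provenance flag.  Balancing is
meant to be applied inside each training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["LabeledDataset", "smote", "rotate_augment"]


@dataclass
class LabeledDataset:
    """Feature vectors with binary labels (0 normal, 1 fractured)."""

    features: np.ndarray                  # (n, d) float
    labels: np.ndarray                    # (n,) int, values in {0, 1}
    case_ids: list[str]
    provenance: list[str] = field(default_factory=list)   # original|synthetic|augmented

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        n = self.features.shape[0]
        if not self.provenance:
            self.provenance = ["original"] * n
        if not (len(self.labels) == len(self.case_ids) == len(self.provenance) == n):
            raise ValueError("parallel lists must have equal length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.features[idx], self.labels[idx],
            [self.case_ids[i] for i in idx],
            [self.provenance[i] for i in idx],
        )


def smote(dataset: LabeledDataset, k_neighbors: int = 5, target_ratio: float = 1.0,
          seed: int = 0, _u_override: float | None = None) -> LabeledDataset:
    """Oversample the minority class to ``target_ratio`` of the majority count.

    ``_u_override`` is a test hook pinning the interpolation coefficient.
    """
    y = dataset.labels
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} samples; SMOTE with k={k_neighbors} "
            f"needs at least {k_neighbors + 1}")
    if not (n_min / n_maj < target_ratio <= 1.0):
        raise ValueError("target_ratio must be in (minority/majority, 1]")
    n_new = int(np.ceil(target_ratio * n_maj)) - n_min

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    X_min = dataset.features[min_idx]
    # k nearest minority neighbors of each minority sample (excluding itself)
    d2 = np.sum((X_min[:, None, :] - X_min[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k_neighbors]

    parents = rng.integers(0, n_min, size=n_new)
    choices = rng.integers(0, k_neighbors, size=n_new)
    u = rng.random(n_new) if _u_override is None else np.full(n_new, _u_override)
    x_par = X_min[parents]
    x_nbr = X_min[nn[parents, choices]]
    X_new = x_par + u[:, None] * (x_nbr - x_par)

    feats = np.vstack([dataset.features, X_new])
    labels = np.concatenate([dataset.labels, np.full(n_new, minority)])
    ids = dataset.case_ids + [f"smote{i:04d}" for i in range(n_new)]
    prov = dataset.provenance + ["synthetic"] * n_new
    return LabeledDataset(feats, labels, ids, prov)


def rotate_augment(image: np.ndarray, masks: list[np.ndarray], angles,
                   seed: int = 0) -> list[tuple[np.ndarray, list[np.ndarray], float]]:
    """Rotate an image and its masks about the image center by each angle.

    Angles must lie in [-15, 15] degrees.  The image is interpolated
    bilinearly, masks with nearest neighbor; labels are carried unchanged by
    the caller.  Returns (rotated image, rotated masks, angle) triples.
    """
    out = []
    for angle in np.atleast_1d(np.asarray(angles, dtype=float)):
        if not -15.0 <= angle <= 15.0:
            raise ValueError(f"rotation angle {angle} outside [-15, 15] degrees")
        img_r = ndimage.rotate(np.asarray(image, dtype=float), angle, reshape=False,
                               order=1, mode="constant", cval=float(np.asarray(image).min()))
        img_r = np.clip(np.rint(img_r), 0, 255).astype(np.uint8)
        masks_r = [
            ndimage.rotate(np.asarray(m, dtype=np.uint8), angle, reshape=False,
                           order=0, mode="constant", cval=0).astype(bool)
            for m in masks
        ]
        out.append((img_r, masks_r, float(angle)))
    return out
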