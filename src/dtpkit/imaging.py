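"""Per-nucleus integrated density from two-channel fluorescence images.

Mirrors the automated confocal quantification used to follow nuclear
protein levels (e.g. nuclear YAP) under treatment: segment nuclei on the
nuclear-stain channel (DAPI-like), then sum the protein channel's pixel
intensities within each nucleus (the integrated density), and normalize
treated measurements by the mean integrated density of a control image to
obtain relative integrated densities.

Segmentation is deliberately simple and fully specified: Otsu global
threshold, hole filling, 8-connected labeling, removal of components
below ``min_area`` pixels (default 50).  There is no watershed splitting
of touching nuclei, so inputs are expected to contain separated nuclei.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import relabel_sequential

__all__ = [
    "segment_nuclei",
    "integrated_density",
    "relative_integrated_density",
]


def segment_nuclei(nuclear_channel: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Segment nuclei in a nuclear-stain channel.

    Returns an integer label map (0 = background, 1..K = nuclei, labels
    contiguous).  A constant image yields zero labels, not an error.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("nuclear channel must be a non-empty 2-D grid")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)
    # drop components with area strictly below min_area
    sizes = np.bincount(labels.ravel())
    too_small = np.nonzero(sizes < min_area)[0]
    labels[np.isin(labels, too_small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def integrated_density(
    labels: np.ndarray, protein_channel: np.ndarray
) -> pd.DataFrame:
    """Sum protein-channel intensity over each labeled nucleus.

    Returns a DataFrame with one row per nucleus: ``label``, ``area``
    (pixels) and ``integrated_density`` (sum of protein pixel values over
    the label's pixels).
    """
    labels = np.asarray(labels)
    protein = np.asarray(protein_channel, dtype=float)
    if labels.shape != protein.shape:
        raise ValueError(
            f"label map shape {labels.shape} != protein channel shape {protein.shape}"
        )
    ids = np.arange(1, labels.max() + 1)
    if ids.size == 0:
        return pd.DataFrame(columns=["label", "area", "integrated_density"])
    areas = ndimage.sum_labels(np.ones_like(protein), labels, index=ids)
    densities = ndimage.sum_labels(protein, labels, index=ids)
    return pd.DataFrame(
        {
            "label": ids,
            "area": areas.astype(int),
            "integrated_density": densities,
        }
    )


def relative_integrated_density(
    treated: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Normalize treated integrated densities by the control mean.

    Each treated nucleus's integrated density is divided by the mean
    integrated density over control nuclei, yielding the dimensionless
    relative integrated density.  Requires a non-empty control with a
    positive mean.
    """
    if len(control) == 0:
        raise ValueError("control measurement table is empty")
    control_mean = float(control["integrated_density"].mean())
    if control_mean <= 0:
        raise ValueError("control mean integrated density must be positive")
    out = treated.copy()
    out["relative_integrated_density"] = out["integrated_density"] / control_mean
    return out
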