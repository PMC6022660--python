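"""Probability-weighted SUV/SUVR computation and amyloid status calling.

The standardized uptake value (SUV) of a region is the grey-matter-
probability-weighted mean of the PET signal over the region mask; the
SUVR is the cortical-target SUV divided by the SUV of a composite
reference region (white matter, whole cerebellum, brainstem and pons).
Weighting each region by its probability map and normalizing by the total
weight keeps the SUVR independent of region size; a ``raw_sum`` mode
returning unnormalized weighted sums is available. Amyloid positivity is
called against a fixed SUVR cutoff (default 0.7585).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AMYLOID_CUTOFF",
    "RegionSpec",
    "weighted_suv",
    "compute_suvr",
    "amyloid_status",
    "normalize_hippocampal_volume",
    "load_volume",
]

AMYLOID_CUTOFF = 0.7585


def load_volume(path) -> np.ndarray:
    """Read a NIfTI volume (.nii / .nii.gz) as a float array."""
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), float)


@dataclass
class RegionSpec:
    """Target/reference region definition for SUVR computation.

    ``gm_probability`` weights the cortical target; the composite
    reference uses uniform weights by default (``reference_weights`` may
    override).
    """

    target_mask: np.ndarray
    reference_mask: np.ndarray
    gm_probability: np.ndarray
    reference_weights: np.ndarray | None = None

    def __post_init__(self):
        tm = np.asarray(self.target_mask)
        rm = np.asarray(self.reference_mask)
        gp = np.asarray(self.gm_probability, float)
        if not (tm.shape == rm.shape == gp.shape):
            raise ValueError("target mask, reference mask and probability map shapes differ")
        if tm.sum() == 0 or rm.sum() == 0:
            raise ValueError("region masks must be non-empty")
        if gp.min() < 0 or gp.max() > 1:
            raise ValueError("grey-matter probabilities must lie in [0, 1]")


def weighted_suv(pet: np.ndarray, weights: np.ndarray, mask: np.ndarray,
                 raw_sum: bool = False) -> float:
    """Weighted SUV of a region.

    Default: sum(w * I) / sum(w) over the mask (invariant to rescaling the
    weights). ``raw_sum=True`` returns the literal weighted sum.
    """
    pet = np.asarray(pet, float)
    weights = np.asarray(weights, float)
    mask = np.asarray(mask).astype(bool)
    if not (pet.shape == weights.shape == mask.shape):
        raise ValueError("pet, weights and mask shapes differ")
    if not np.isfinite(pet[mask]).all():
        raise ValueError("non-finite PET intensities inside the mask")
    w = weights[mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight inside the mask")
    num = float((w * pet[mask]).sum())
    return num if raw_sum else num / float(total)


def compute_suvr(pet: np.ndarray, region: RegionSpec, raw_sum: bool = False) -> float:
    """SUVR: target-region SUV divided by reference-region SUV."""
    suv_t = weighted_suv(pet, region.gm_probability, region.target_mask, raw_sum=raw_sum)
    ref_w = (region.reference_weights if region.reference_weights is not None
             else np.ones_like(np.asarray(pet, float)))
    suv_r = weighted_suv(pet, ref_w, region.reference_mask, raw_sum=raw_sum)
    if suv_r == 0:
        raise ValueError("reference-region SUV is zero")
    return suv_t / suv_r


def amyloid_status(suvr: float, cutoff: float = AMYLOID_CUTOFF) -> str:
    """Amyloid status: 'positive' iff SUVR strictly exceeds the cutoff."""
    if not suvr > 0:
        raise ValueError("SUVR must be positive")
    return "positive" if suvr > cutoff else "negative"


def normalize_hippocampal_volume(hv: float, icv: float) -> float:
    """Hippocampal volume normalized by total intracranial volume."""
    if icv <= 0:
        raise ValueError("intracranial volume must be positive")
    if hv < 0:
        raise ValueError("hippocampal volume must be non-negative")
    return hv / icv
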