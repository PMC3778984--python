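"""ROI statistics on fractional-anisotropy volumes.

Hemispheric mean FA over internal-capsule ROIs, the FA asymmetry index

    asym = (FA_unaffected - FA_affected) / (FA_unaffected + FA_affected),

lesion volume in mm^3, and the overlap between a lesion mask and a
thresholded corticospinal-tract probability map. All volumes entering one
computation must share grid shape, voxel dimensions and space tag;
registration/warping is out of scope (inputs are assumed pre-aligned).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: default CST probability threshold, as a fraction of the map maximum
DEFAULT_CST_THRESHOLD_FRAC = 0.1


@dataclass(frozen=True)
class LabeledVolume:
    """A scalar voxel grid (FA, probability, or binary mask) with geometry."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    space: str = "synthetic-common"

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([*self.voxel_dims, 1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.voxel_dims)
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, space: str = "synthetic-common") -> "LabeledVolume":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj, dtype=float), zooms, space)


def _check_same_grid(a: LabeledVolume, b: LabeledVolume) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(
            f"grid mismatch: {a.data.shape} vs {b.data.shape}"
        )
    if not np.allclose(a.voxel_dims, b.voxel_dims):
        raise ValueError(
            f"voxel_dims mismatch: {a.voxel_dims} vs {b.voxel_dims}"
        )
    if a.space != b.space:
        raise ValueError(f"space mismatch: {a.space!r} vs {b.space!r}")


def _as_bool_mask(mask: LabeledVolume) -> np.ndarray:
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("mask must be strictly binary (0/1 voxels)")
    return mask.data.astype(bool)


def roi_mean(fa_volume: LabeledVolume, mask: LabeledVolume) -> float:
    """Arithmetic mean FA over the mask voxels."""
    _check_same_grid(fa_volume, mask)
    m = _as_bool_mask(mask)
    if not m.any():
        raise ValueError("empty ROI mask")
    return float(fa_volume.data[m].mean())


def fa_asymmetry(fa_unaffected: float, fa_affected: float) -> float:
    """Normalized interhemispheric FA difference in [-1, 1].

    0 for symmetric hemispheres; approaches 1 as the affected-hemisphere
    FA vanishes relative to the unaffected side.
    """
    total = fa_unaffected + fa_affected
    if total == 0:
        raise ValueError("FA asymmetry undefined when both means are zero")
    return (fa_unaffected - fa_affected) / total


def mask_volume_mm3(mask: LabeledVolume) -> float:
    """Voxel count times voxel volume, in mm^3."""
    return float(_as_bool_mask(mask).sum()) * mask.voxel_volume_mm3


def lesion_cst_overlap(
    lesion_mask: LabeledVolume,
    cst_prob_map: LabeledVolume,
    prob_threshold: float | None = None,
) -> float:
    """Volume (mm^3) of lesion voxels lying on the thresholded CST.

    ``prob_threshold`` is an absolute probability in [0, 1]; when omitted
    it defaults to 10% of the map maximum. A voxel counts when it is in
    the lesion mask AND its CST probability is >= the threshold.
    """
    _check_same_grid(lesion_mask, cst_prob_map)
    prob = cst_prob_map.data
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("CST probability map values must lie in [0, 1]")
    if prob_threshold is None:
        prob_threshold = DEFAULT_CST_THRESHOLD_FRAC * float(prob.max())
    if not 0 <= prob_threshold <= 1:
        raise ValueError(f"prob_threshold {prob_threshold} outside [0, 1]")
    lesion = _as_bool_mask(lesion_mask)
    overlap = lesion & (prob >= prob_threshold)
    return float(overlap.sum()) * lesion_mask.voxel_volume_mm3


@dataclass(frozen=True)
class ROIStats:
    """Per-hemisphere mean FA and asymmetry for one ROI pair."""

    roi_name: str            # {"PLIC", "ALIC"}
    fa_affected: float
    fa_unaffected: float

    @property
    def fa_asymmetry(self) -> float:
        return fa_asymmetry(self.fa_unaffected, self.fa_affected)


def roi_stats(
    fa_volume: LabeledVolume,
    mask_affected: LabeledVolume,
    mask_unaffected: LabeledVolume,
    roi_name: str,
) -> ROIStats:
    """Mean FA in homologous affected/unaffected ROIs plus their asymmetry."""
    return ROIStats(
        roi_name=roi_name,
        fa_affected=roi_mean(fa_volume, mask_affected),
        fa_unaffected=roi_mean(fa_volume, mask_unaffected),
    )
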