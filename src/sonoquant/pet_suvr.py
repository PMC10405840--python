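"""PET standardized-uptake-value-ratio (SUVr) quantification.

SUVr of a target region is its mean uptake divided by the mean uptake of a
reference region (here the role the whole cerebellum plays clinically),
computed on a caller-supplied integer label volume co-registered with the
PET.  Percent change between timepoints is 100·(followup/baseline − 1), so
a reduction is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import RasterVolume

__all__ = ["SUVrResult", "SUVrChange", "compute_suvr", "suvr_change"]


@dataclass
class SUVrResult:
    roi_suvr: float
    roi_mean: float
    reference_mean: float
    roi_id: int
    reference_ids: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "roi_suvr": self.roi_suvr,
            "roi_mean": self.roi_mean,
            "reference_mean": self.reference_mean,
            "roi_id": self.roi_id,
            "reference_ids": list(self.reference_ids),
        }


@dataclass
class SUVrChange:
    """Percent SUVr change relative to baseline (reduction = negative)."""

    percent_change: float
    baseline_suvr: float
    followup_suvr: float
    roi_id: int


def compute_suvr(
    pet: RasterVolume,
    labels: RasterVolume,
    roi_id: int,
    reference_ids: Sequence[int],
) -> SUVrResult:
    """Mean uptake in the target region over mean uptake in the reference.

    The reference mean is the unweighted voxel mean over all voxels whose
    label is in ``reference_ids``.  Invariant under any positive global
    rescaling of the PET volume.
    """
    if pet.data.shape != labels.data.shape:
        raise ValueError(
            f"PET grid {pet.data.shape} and label grid {labels.data.shape} differ"
        )
    lab = labels.data
    roi_mask = lab == roi_id
    ref_mask = np.isin(lab, np.asarray(list(reference_ids)))
    if not roi_mask.any():
        raise ValueError(f"target region {roi_id} has no voxels in the label volume")
    if not ref_mask.any():
        raise ValueError(f"reference regions {tuple(reference_ids)} have no voxels")
    roi_mean = float(pet.data[roi_mask].mean())
    ref_mean = float(pet.data[ref_mask].mean())
    if ref_mean <= 0:
        raise ValueError("reference region has non-positive mean uptake")
    return SUVrResult(
        roi_suvr=roi_mean / ref_mean,
        roi_mean=roi_mean,
        reference_mean=ref_mean,
        roi_id=int(roi_id),
        reference_ids=tuple(int(r) for r in reference_ids),
    )


def suvr_change(baseline: SUVrResult, followup: SUVrResult) -> SUVrChange:
    """Percent change 100·(followup/baseline − 1) for the same target region."""
    if baseline.roi_id != followup.roi_id:
        raise ValueError(
            f"ROI mismatch: baseline {baseline.roi_id} vs follow-up {followup.roi_id}"
        )
    return SUVrChange(
        percent_change=100.0 * (followup.roi_suvr / baseline.roi_suvr - 1.0),
        baseline_suvr=baseline.roi_suvr,
        followup_suvr=followup.roi_suvr,
        roi_id=baseline.roi_id,
    )
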