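"""Core containers shared across the pipeline.

Volumes are numpy arrays indexed ``(x, y, z)`` with ``z`` the slice axis;
"slice-wise" operations act on axial planes ``volume[:, :, k]``.  Physical
units are millimetres throughout; voxel size is the edge length per axis, so
anisotropic clinical grids (e.g. 2 x 2 x 5 mm) are supported everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

MODALITIES = ("T1w", "DWI", "FLAIR")


class Tissue(IntEnum):
    """Label codes used in every label volume."""

    BACKGROUND = 0
    GM = 1
    WM = 2
    CSF = 3
    ABT_HYPER = 4  # DWI-hyperintense abnormal tissue
    ABT_ISO = 5    # DWI iso-/hypointense abnormal tissue


#: classes forming the abnormal-brain-tissue object
ABT_CLASSES = (Tissue.ABT_HYPER, Tissue.ABT_ISO)


@dataclass
class MultimodalStudy:
    """Co-registered scalar volumes for one subject.

    Parameters
    ----------
    modalities
        Mapping from modality name (``T1w``, ``DWI``, ``FLAIR``; optionally
        ``T1w_pre`` / ``T1w_post`` for the contrast pair) to a 3-D volume.
    voxel_size
        Physical voxel edge lengths in mm per axis.
    voi
        Boolean skull-peeled volume of interest, or ``None`` if not yet built.
    class_probabilities
        Optional mapping ``{"GM", "WM", "CSF"} -> probability volume`` used to
        initialise the tissue classes (supplied by the phantom generator in
        place of atlas-based priors).
    """

    modalities: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    voi: np.ndarray | None = None
    class_probabilities: dict[str, np.ndarray] | None = None
    subject_id: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.modalities.values())).shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        """RAS affine encoding the voxel size (origin at grid corner)."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.modalities]
        if missing:
            raise KeyError(f"study is missing modalities: {', '.join(missing)}")


@dataclass
class GroundTruth:
    """Known phantom truth used to score the pipeline."""

    label_volume: np.ndarray                  # Tissue codes
    bbbd_mask: np.ndarray                     # boolean
    enhancement_truth: np.ndarray             # relative enhancement >= 0
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def abt_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, ABT_CLASSES)

    @property
    def voi_mask(self) -> np.ndarray:
        return self.label_volume != Tissue.BACKGROUND


@dataclass
class SegmentationResult:
    """Final output of the five-class segmentation."""

    labels: np.ndarray                        # Tissue codes on the VOI
    posteriors: np.ndarray                    # (N_voi, K) EM posteriors
    voi: np.ndarray
    abt_mask: np.ndarray                      # final refined ABT object
    abt_subdivision: np.ndarray               # Tissue codes 4/5 inside abt_mask
    initial_lesion: np.ndarray
    log: dict = field(default_factory=dict)   # provenance: parameters per stage


@dataclass
class BBBDResult:
    """Blood-brain-barrier dysfunction detection output."""

    mask: np.ndarray
    map: np.ndarray                           # normalised 0-1 enhancement map
    tau1: float
    tau2: float
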