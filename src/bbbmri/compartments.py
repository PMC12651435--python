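"""Compartment bookkeeping and perilesional distance-ring analysis.

The intracranial volume (ICV) is partitioned into normal brain tissue (NBT),
abnormal brain tissue (ABT) and CSF space; NBT and ABT are each split by the
BBBD mask into barrier-dysfunctional and intact-barrier fractions, reported
as percentages of ICV.  The vicinity analysis assigns every NBT voxel its
Euclidean distance (physical mm, anisotropy respected) to the nearest ABT
voxel and bins it into half-open rings [0,1), [1,2), [2,3) cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class CompartmentSummary:
    """Five-compartment split as % of total intracranial volume."""

    NBT_iBBB_pct: float
    NBT_BBBD_pct: float
    ABT_iBBB_pct: float
    ABT_BBBD_pct: float
    CSF_pct: float
    icv_mm3: float

    def as_dict(self) -> dict[str, float]:
        return {"NBT_iBBB_pct": self.NBT_iBBB_pct, "NBT_BBBD_pct": self.NBT_BBBD_pct,
                "ABT_iBBB_pct": self.ABT_iBBB_pct, "ABT_BBBD_pct": self.ABT_BBBD_pct,
                "CSF_pct": self.CSF_pct, "icv_mm3": self.icv_mm3}


@dataclass
class RingZone:
    name: str
    tissue_mm3: float
    bbbd_mm3: float

    @property
    def bbbd_fraction_pct(self) -> float:
        return 100.0 * self.bbbd_mm3 / self.tissue_mm3 if self.tissue_mm3 > 0 else 0.0


def compartment_summary(nbt_mask: np.ndarray, abt_mask: np.ndarray,
                        csf_mask: np.ndarray, bbbd_mask: np.ndarray,
                        voxel_size: tuple[float, ...]) -> CompartmentSummary:
    """Volumes and ICV percentages of the five compartments.

    ICV is the union of NBT, ABT and CSF; the three masks must be disjoint.
    """
    nbt, abt, csf = (m.astype(bool) for m in (nbt_mask, abt_mask, csf_mask))
    if (nbt & abt).any() or (nbt & csf).any() or (abt & csf).any():
        raise ValueError("NBT, ABT and CSF masks must be disjoint")
    bbbd = bbbd_mask.astype(bool)
    vv = float(np.prod(voxel_size))
    icv_vox = int(nbt.sum() + abt.sum() + csf.sum())
    if icv_vox == 0:
        raise ValueError("intracranial volume is empty")
    icv = icv_vox * vv

    def pct(mask):
        return 100.0 * mask.sum() * vv / icv

    return CompartmentSummary(
        NBT_iBBB_pct=pct(nbt & ~bbbd), NBT_BBBD_pct=pct(nbt & bbbd),
        ABT_iBBB_pct=pct(abt & ~bbbd), ABT_BBBD_pct=pct(abt & bbbd),
        CSF_pct=pct(csf), icv_mm3=icv)


def distance_rings(abt_mask: np.ndarray, nbt_mask: np.ndarray,
                   voxel_size: tuple[float, ...],
                   bounds_mm: tuple[float, ...] = (10.0, 20.0, 30.0)
                   ) -> list[np.ndarray]:
    """Ring masks of NBT voxels binned by distance to the ABT object.

    Distances come from the exact Euclidean distance transform with the voxel
    size as sampling, so they are physical millimetres; intervals are
    lower-inclusive half-open, e.g. a voxel at exactly 10 mm falls in the
    second ring.
    """
    abt = abt_mask.astype(bool)
    if not abt.any():
        raise ValueError("ABT mask is empty: rings are undefined")
    nbt = nbt_mask.astype(bool)
    dist = ndimage.distance_transform_edt(~abt, sampling=voxel_size)
    rings = []
    lo = 0.0
    for hi in bounds_mm:
        rings.append(nbt & (dist >= lo) & (dist < hi))
        lo = hi
    return rings


def ring_bbbd_stats(rings: list[np.ndarray], abt_mask: np.ndarray,
                    bbbd_mask: np.ndarray, voxel_size: tuple[float, ...],
                    bounds_mm: tuple[float, ...] = (10.0, 20.0, 30.0)
                    ) -> list[RingZone]:
    """Per zone (ABT itself plus each ring): volume, BBBD volume, BBBD %."""
    vv = float(np.prod(voxel_size))
    bbbd = bbbd_mask.astype(bool)
    zones = [RingZone("ABT", abt_mask.sum() * vv, (abt_mask.astype(bool) & bbbd).sum() * vv)]
    lo = 0.0
    for ring, hi in zip(rings, bounds_mm):
        name = f"NBT {lo / 10:g}-{hi / 10:g} cm"
        zones.append(RingZone(name, ring.sum() * vv, (ring & bbbd).sum() * vv))
        lo = hi
    return zones
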