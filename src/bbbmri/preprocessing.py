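"""Skull-peeled VOI construction, z-score transform and control templates.

Intensities are compared across scanners in z-score space: each image is
standardised by the mean and SD of its own intensities inside the
skull-peeled volume of interest (VOI).  For patient FLAIR the estimation of
mu/sigma trims the top lambda fraction of intensities (default 3%) because
large hyperintense lesions would otherwise inflate them; the transform itself
is still applied to every VOI voxel.  Healthy-control templates are the
voxelwise mean and unbiased variance of the controls' z-scored images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import MODALITIES, MultimodalStudy


@dataclass
class VOIMask:
    mask: np.ndarray
    source: str = "GM+WM+CSF>=0.5, largest component"


@dataclass
class ZScoreVolume:
    values: np.ndarray            # z-scores, zero outside the VOI
    voi: np.ndarray
    mu: float
    sigma: float
    trim_fraction: float


@dataclass
class TemplateSet:
    """Voxelwise mean/variance per modality across controls, z-score space."""

    mean: dict[str, np.ndarray]
    variance: dict[str, np.ndarray]
    voi: np.ndarray
    n_controls: int
    variance_floor: float = 1e-6
    modalities: tuple[str, ...] = MODALITIES


def make_voi_mask(class_probability_volumes: dict[str, np.ndarray],
                  threshold: float = 0.5) -> VOIMask:
    """VOI = voxels with GM+WM+CSF probability >= threshold, largest component kept."""
    total = sum(class_probability_volumes[k] for k in ("GM", "WM", "CSF"))
    mask = total >= threshold
    if not mask.any():
        raise ValueError("VOI mask is empty: no voxel reaches the probability threshold")
    labelled, n = ndimage.label(mask)
    if n > 1:
        counts = np.bincount(labelled.ravel())
        counts[0] = 0
        mask = labelled == int(np.argmax(counts))
    return VOIMask(mask=mask)


def zscore_image(volume: np.ndarray, voi: np.ndarray | VOIMask,
                 trim_fraction: float = 0.0) -> ZScoreVolume:
    """Standardise an image over the VOI.

    ``trim_fraction`` (lambda) removes the top fraction of intensities from
    the *estimation* of mu and sigma only; all VOI voxels, including trimmed
    ones, are transformed.  Trimming keeps the lower ``ceil((1-lambda)*n)``
    order statistics, so lambda=0.03 on values 1..100 estimates from 1..97.
    """
    mask = voi.mask if isinstance(voi, VOIMask) else voi.astype(bool)
    if not mask.any():
        raise ValueError("VOI is empty")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim fraction must lie in [0, 0.5)")
    vals = volume[mask].astype(float)
    if trim_fraction > 0:
        n_keep = int(np.ceil((1.0 - trim_fraction) * vals.size))
        vals = np.sort(vals)[:n_keep]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    if sigma == 0:
        raise ValueError("constant image over the VOI: sigma is 0")
    z = np.zeros_like(volume, dtype=np.float64)
    z[mask] = (volume[mask] - mu) / sigma
    return ZScoreVolume(values=z, voi=mask, mu=mu, sigma=sigma,
                        trim_fraction=trim_fraction)


def build_templates(controls: list[MultimodalStudy], voi: np.ndarray | VOIMask,
                    variance_floor: float = 1e-6,
                    modalities: tuple[str, ...] = MODALITIES) -> TemplateSet:
    """Voxelwise mean/variance of the controls' z-scored images.

    Controls are lesion-free, so no trimming is applied to them.  Variance is
    the unbiased (n-1) estimator, floored at ``variance_floor`` to keep the
    downstream Mahalanobis distances finite.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 controls to estimate template variance")
    mask = voi.mask if isinstance(voi, VOIMask) else voi.astype(bool)
    shape = controls[0].shape
    for c in controls:
        if c.shape != shape:
            raise ValueError(f"control {c.subject_id!r} grid {c.shape} != {shape}")
        c.require(*modalities)
    mean: dict[str, np.ndarray] = {}
    variance: dict[str, np.ndarray] = {}
    for m in modalities:
        stack = np.stack([zscore_image(c.modalities[m], mask).values for c in controls])
        mean[m] = stack.mean(axis=0)
        variance[m] = np.maximum(stack.var(axis=0, ddof=1), variance_floor)
    return TemplateSet(mean=mean, variance=variance, voi=mask,
                       n_controls=len(controls), variance_floor=variance_floor,
                       modalities=modalities)
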