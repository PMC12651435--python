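"""Blood-brain-barrier dysfunction (BBBD) mapping from a pre/post contrast pair.

Contrast leakage is detected by comparing each voxel's relative enhancement
``E = (post - pre) / pre`` against two thresholds derived from reference
tissues: tau1, the density intersection of the vitreous-body and muscle
enhancement Gaussians (separating noise from physiological enhancement), and
tau2, the muscle/vessel intersection (separating parenchymal leakage from
intravascular tracer).  Voxels with tau1 <= E <= tau2 seed the BBBD object;
clusters below four voxels are discarded and the object is grown into an
expanded band 0.5*tau1 - 1.5*tau2 through 8-connected neighbours.  The final
map re-assigns each BBBD voxel its enhancement level, min-max normalised to
0-1.  Range endpoints are inclusive throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .types import BBBDResult

logger = logging.getLogger(__name__)

#: slice-wise 8-connectivity: full in-plane neighbourhood, no coupling across slices
STRUCT_2D8 = np.zeros((3, 3, 3), dtype=bool)
STRUCT_2D8[:, :, 1] = True
#: 3-D 26-connectivity alternative
STRUCT_3D26 = np.ones((3, 3, 3), dtype=bool)


def _structure(connectivity_3d: bool) -> np.ndarray:
    return STRUCT_3D26 if connectivity_3d else STRUCT_2D8


@dataclass
class GaussianFit:
    mean: float
    sd: float
    roi_label: str = ""
    n_voxels: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("Gaussian SD must be > 0")


def compute_enhancement(pre: np.ndarray, post: np.ndarray,
                        voi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative enhancement ``(post - pre) / pre`` on the VOI.

    Returns ``(E, valid)`` where ``valid`` is the VOI restricted to voxels
    with positive pre-contrast intensity; excluded-voxel counts are logged.
    ``E`` is zero outside ``valid``.
    """
    voi = voi.astype(bool)
    if not voi.any():
        raise ValueError("VOI is empty")
    valid = voi & (pre > 0)
    if not valid.any():
        raise ValueError("no voxel with positive pre-contrast intensity in VOI")
    n_excluded = int(voi.sum() - valid.sum())
    if n_excluded:
        logger.info("enhancement undefined at %d VOI voxels (pre <= 0); excluded", n_excluded)
    E = np.zeros_like(pre, dtype=np.float64)
    E[valid] = (post[valid] - pre[valid]) / pre[valid]
    return E, valid


def fit_roi_gaussian(values: np.ndarray, roi_label: str = "") -> GaussianFit:
    """Gaussian fitted by least squares to the normalised ROI histogram.

    Bins follow the Freedman-Diaconis rule; the fit is initialised at the
    sample moments and falls back to them (with a log message) if the
    optimiser fails.  Requires at least 30 voxels.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 30:
        raise ValueError(f"ROI {roi_label!r} too small ({values.size} voxels; need >= 30)")
    mu0, sd0 = float(values.mean()), float(values.std(ddof=1))
    if sd0 == 0:
        raise ValueError(f"ROI {roi_label!r} is constant; Gaussian SD would be 0")
    counts, edges = np.histogram(values, bins="fd", density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sd):
        return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (np.abs(sd) * np.sqrt(2 * np.pi))

    try:
        popt, _ = optimize.curve_fit(gauss, centres, counts, p0=(mu0, sd0), maxfev=2000)
        mu, sd = float(popt[0]), float(abs(popt[1]))
        converged = np.isfinite(mu) and np.isfinite(sd) and sd > 0
    except (RuntimeError, ValueError):
        converged = False
    if not converged:
        logger.info("histogram fit for ROI %r did not converge; using sample moments", roi_label)
        mu, sd = mu0, sd0
    return GaussianFit(mean=mu, sd=sd, roi_label=roi_label,
                       n_voxels=int(values.size), converged=converged)


def gaussian_intersection_params(m1: float, s1: float, m2: float, s2: float) -> float:
    """Equal-density point of two Gaussians, the root between the means.

    Equal SDs give the midpoint; otherwise the quadratic in x from equating
    log-densities is solved and the root strictly between the means returned.
    """
    if not m1 < m2:
        raise ValueError("require mean1 < mean2 (equal means have no usable intersection)")
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log(s2 / s1)
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise ValueError("Gaussian densities do not intersect between the means")
    roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
    between = [r for r in roots if m1 < r < m2]
    if not between:
        raise ValueError("no density intersection strictly between the two means "
                         "(pathologically nested distributions)")
    return float(between[0])


def gaussian_intersection(g1: GaussianFit, g2: GaussianFit) -> float:
    """Intersection of two fitted ROI Gaussians (``g1`` must have lower mean)."""
    return gaussian_intersection_params(g1.mean, g1.sd, g2.mean, g2.sd)


def estimate_thresholds(E: np.ndarray, roi_masks: dict[str, np.ndarray]
                        ) -> tuple[float, float]:
    """tau1/tau2 from the vitreous, muscle and vessel reference ROIs."""
    fits = {name: fit_roi_gaussian(E[roi_masks[name]], name)
            for name in ("vitreous", "muscle", "vessel")}
    tau1 = gaussian_intersection(fits["vitreous"], fits["muscle"])
    tau2 = gaussian_intersection(fits["muscle"], fits["vessel"])
    return tau1, tau2


def detect_bbbd(E: np.ndarray, valid: np.ndarray, tau1: float, tau2: float,
                min_cluster: int = 4, connectivity_3d: bool = False) -> np.ndarray:
    """Seed mask: tau1 <= E <= tau2 with small clusters removed.

    Connected components (slice-wise 8-connectivity by default) with fewer
    than ``min_cluster`` voxels are discarded.
    """
    if not tau1 < tau2:
        raise ValueError("require tau1 < tau2")
    seed = valid & (E >= tau1) & (E <= tau2)
    if not seed.any():
        return seed
    labelled, n = ndimage.label(seed, structure=_structure(connectivity_3d))
    counts = np.bincount(labelled.ravel())
    keep = np.flatnonzero(counts >= min_cluster)
    keep = keep[keep > 0]
    return np.isin(labelled, keep)


def expand_bbbd(seed_mask: np.ndarray, E: np.ndarray, valid: np.ndarray,
                tau1: float, tau2: float, expand_low: float = 0.5,
                expand_high: float = 1.5, connectivity_3d: bool = False) -> np.ndarray:
    """Grow the seed into the expanded band ``expand_low*tau1 <= E <= expand_high*tau2``.

    8-connected neighbours inside the band are appended iteratively until a
    fixed point; the result always contains the seed and never leaves the band
    (except for the seed voxels themselves, which are kept verbatim).
    """
    band = valid & (E >= expand_low * tau1) & (E <= expand_high * tau2)
    struct = _structure(connectivity_3d)
    mask = seed_mask.copy()
    while True:
        frontier = ndimage.binary_dilation(mask, structure=struct) & band & ~mask
        if not frontier.any():
            return mask
        mask |= frontier


def make_enhancement_map(final_mask: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Min-max normalised enhancement inside the mask, zero outside."""
    out = np.zeros_like(E, dtype=np.float64)
    if not final_mask.any():
        return out
    vals = E[final_mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        warnings.warn("degenerate enhancement range over BBBD mask; map set to 1",
                      stacklevel=2)
        out[final_mask] = 1.0
        return out
    out[final_mask] = (E[final_mask] - lo) / (hi - lo)
    return out


def map_bbbd(pre: np.ndarray, post: np.ndarray, voi: np.ndarray,
             roi_masks: dict[str, np.ndarray], min_cluster: int = 4,
             expand_low: float = 0.5, expand_high: float = 1.5,
             connectivity_3d: bool = False) -> BBBDResult:
    """Full BBBD pipeline: enhancement, thresholds, detection, expansion, map."""
    # ROIs sit outside the brain VOI, so evaluate enhancement where pre > 0
    roi_union = np.zeros_like(voi, dtype=bool)
    for m in roi_masks.values():
        roi_union |= m
    E, valid = compute_enhancement(pre, post, voi | roi_union)
    tau1, tau2 = estimate_thresholds(E, roi_masks)
    brain_valid = valid & voi.astype(bool)
    seed = detect_bbbd(E, brain_valid, tau1, tau2, min_cluster, connectivity_3d)
    final = expand_bbbd(seed, E, brain_valid, tau1, tau2,
                        expand_low, expand_high, connectivity_3d)
    return BBBDResult(mask=final, map=make_enhancement_map(final, E),
                      tau1=tau1, tau2=tau2)
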