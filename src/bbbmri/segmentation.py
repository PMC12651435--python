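"""Five-class segmentation of abnormal brain tissue (ABT).

The pipeline: per-modality Mahalanobis outliers against healthy-control
templates seed two candidate lesion classes (split into DWI-hyperintense and
iso-/hypointense by k-means); a five-class Gaussian-mixture model on
PCA-reduced multimodal features is refined by expectation-maximisation;
voxels take the maximum-posterior label; the ABT object is then grown into
qualifying 8-connected neighbours and polished morphologically.

Connectivity conventions: "8-connected" is two-dimensional within axial
slices (matching the slice-wise morphology); the small-component filter uses
3-D 26-connectivity since its threshold is a physical volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .preprocessing import TemplateSet, ZScoreVolume, make_voi_mask, zscore_image
from .types import MultimodalStudy, SegmentationResult, Tissue

logger = logging.getLogger(__name__)

_STRUCT_2D8 = np.zeros((3, 3, 3), dtype=bool)
_STRUCT_2D8[:, :, 1] = True
_STRUCT_3D26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class OutlierResult:
    """Per-modality template distances and the initial lesion estimate."""

    distances: dict[str, np.ndarray]
    threshold: float
    initial_lesion: np.ndarray


@dataclass
class GMMState:
    """Gaussian-mixture parameters and posteriors after EM."""

    means: np.ndarray                 # (K, M)
    covariances: np.ndarray           # (K, M, M)
    weights: np.ndarray               # (K,)
    gamma: np.ndarray                 # (N, K) posteriors, rows sum to 1
    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


# -- initialisation ---------------------------------------------------------

def mahalanobis_distance(z_patient: ZScoreVolume, template: TemplateSet,
                         modality: str) -> np.ndarray:
    """Voxelwise distance ``|z - template_mean| / sqrt(template_variance)``.

    The template covariance is per-modality across control subjects, so the
    distance reduces to a scaled absolute deviation in one dimension.
    """
    if z_patient.values.shape != template.mean[modality].shape:
        raise ValueError("patient volume and template grids differ")
    d = np.zeros_like(z_patient.values)
    voi = z_patient.voi
    d[voi] = np.abs(z_patient.values[voi] - template.mean[modality][voi]) \
        / np.sqrt(template.variance[modality][voi])
    return d


def initial_lesion(distances: dict[str, np.ndarray], voi: np.ndarray,
                   threshold: float = 3.0) -> np.ndarray:
    """Aggregate outliers: a voxel is lesion if any modality distance >= threshold."""
    if not distances:
        raise ValueError("need at least one modality distance volume")
    mask = np.zeros_like(voi, dtype=bool)
    for d in distances.values():
        mask |= d >= threshold
    return mask & voi.astype(bool)


def split_lesion_by_dwi(lesion_mask: np.ndarray, dwi_volume: np.ndarray) -> np.ndarray:
    """k-means (k=2) on DWI intensities of lesion voxels.

    The cluster with the higher mean is labelled DWI-hyperintense (class 4),
    the other iso-/hypointense (class 5).  Initial centroids are the minimum
    and maximum intensity, making the split deterministic.  Degenerate lesions
    (fewer than two distinct values) are assigned entirely to the iso class
    with a warning.
    """
    labels = np.zeros(lesion_mask.shape, dtype=np.int16)
    vals = dwi_volume[lesion_mask].astype(float)
    if vals.size == 0:
        return labels
    if np.unique(vals).size < 2:
        warnings.warn("lesion has < 2 distinct DWI values; assigned to the iso class",
                      stacklevel=2)
        labels[lesion_mask] = Tissue.ABT_ISO
        return labels
    init = np.array([[vals.min()], [vals.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300).fit(vals[:, None])
    hyper_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    assign = np.where(km.labels_ == hyper_cluster, Tissue.ABT_HYPER, Tissue.ABT_ISO)
    labels[lesion_mask] = assign
    return labels


# -- feature reduction and EM ----------------------------------------------

def pca_reduce(X: np.ndarray, variance_threshold: float = 0.05) -> np.ndarray:
    """Project z-scored features onto principal axes, keeping components that
    explain at least ``variance_threshold`` of the total variance (>= 1 kept)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] <= X.shape[1]:
        raise ValueError("feature matrix must be N x M with N > M")
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("rank-0 feature matrix")
    pca = PCA(n_components=X.shape[1]).fit(X)
    frac = pca.explained_variance_ratio_
    keep = max(1, int(np.sum(frac >= variance_threshold)))
    return pca.transform(X)[:, :keep]


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log multivariate normal density, via Cholesky."""
    M = x.shape[1]
    L = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(L, diff.T)
    maha2 = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (M * np.log(2 * np.pi) + logdet + maha2)


def em_gmm(scores: np.ndarray, initial_labels: np.ndarray, K: int = 5,
           tol: float = 1e-6, max_iter: int = 100,
           covariance_floor: float = 1e-6) -> GMMState:
    """Expectation-maximisation for a K-component Gaussian mixture.

    Parameters are initialised from the per-class statistics of
    ``initial_labels`` (values 0..K-1).  Each class must start with at least
    M+1 members so its covariance is estimable.  E and M steps alternate until
    the relative log-likelihood change drops below ``tol`` or ``max_iter``
    iterations; covariances are regularised by ``covariance_floor * I``.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, M = X.shape
    labels = np.asarray(initial_labels).ravel()
    if labels.size != N:
        raise ValueError("initial labels must match the number of feature rows")

    means = np.zeros((K, M))
    covs = np.zeros((K, M, M))
    weights = np.zeros(K)
    eye = covariance_floor * np.eye(M)
    for k in range(K):
        members = X[labels == k]
        if members.shape[0] < M + 1:
            raise ValueError(f"initial class {k} has {members.shape[0]} members; "
                             f"need at least {M + 1}")
        means[k] = members.mean(axis=0)
        covs[k] = np.cov(members, rowvar=False, ddof=0).reshape(M, M) + eye
        weights[k] = members.shape[0] / N

    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_dens = np.column_stack([
            np.log(weights[k]) + _log_gauss(X, means[k], covs[k]) for k in range(K)])
        top = log_dens.max(axis=1, keepdims=True)
        lse = top[:, 0] + np.log(np.exp(log_dens - top).sum(axis=1))
        gamma = np.exp(log_dens - lse[:, None])
        ll = float(lse.sum())
        ll_trace.append(ll)
        if len(ll_trace) > 1:
            prev = ll_trace[-2]
            if abs(ll - prev) < tol * abs(prev):
                converged = True
                break
        # M-step
        Nk = gamma.sum(axis=0)
        weights = Nk / N
        for k in range(K):
            means[k] = gamma[:, k] @ X / Nk[k]
            diff = X - means[k]
            covs[k] = (gamma[:, k] * diff.T) @ diff / Nk[k] + eye
    return GMMState(means=means, covariances=covs, weights=weights,
                    gamma=gamma, log_likelihood=ll_trace, n_iter=it,
                    converged=converged)


def map_labels(gamma: np.ndarray) -> np.ndarray:
    """Maximum-posterior class per row; ties break to the lowest class index."""
    return np.argmax(gamma, axis=1)


# -- spatial refinement -----------------------------------------------------

def region_grow_abt(labels: np.ndarray, gamma_vol: np.ndarray, voi: np.ndarray,
                    margin: float = 0.1, sum_threshold: float = 0.5) -> np.ndarray:
    """Grow the ABT object into qualifying 8-connected in-slice neighbours.

    A GM/WM/CSF voxel adjacent to the current ABT is re-labelled ABT when any
    criterion holds: the gap between its maximum posterior and gamma4 (or
    gamma5) is strictly below ``margin``, or gamma4+gamma5 >= ``sum_threshold``
    (boundary inclusive).  Grown voxels take the ABT class with the larger
    posterior.  Updates are synchronous per iteration, so the fixed point is
    independent of voxel order.
    """
    labels = labels.copy()
    gmax = gamma_vol.max(axis=-1)
    g4 = gamma_vol[..., Tissue.ABT_HYPER - 1]
    g5 = gamma_vol[..., Tissue.ABT_ISO - 1]
    qualifies = ((gmax - g4 < margin) | (gmax - g5 < margin)
                 | (g4 + g5 >= sum_threshold))
    eligible = np.isin(labels, (Tissue.GM, Tissue.WM, Tissue.CSF)) & voi.astype(bool)
    abt = np.isin(labels, (Tissue.ABT_HYPER, Tissue.ABT_ISO))
    while True:
        neighbours = ndimage.binary_dilation(abt, structure=_STRUCT_2D8) & ~abt
        grow = neighbours & eligible & qualifies
        if not grow.any():
            break
        labels[grow] = np.where(g4[grow] >= g5[grow], Tissue.ABT_HYPER, Tissue.ABT_ISO)
        abt |= grow
        eligible &= ~grow
    return labels


def remove_small_components(mask: np.ndarray, voxel_size: tuple[float, ...],
                            min_mm3: float = 3.0) -> np.ndarray:
    """Delete 3-D 26-connected components with physical volume < min_mm3 (strict)."""
    if not mask.any():
        return mask.copy()
    voxel_volume = float(np.prod(voxel_size))
    labelled, _ = ndimage.label(mask, structure=_STRUCT_3D26)
    counts = np.bincount(labelled.ravel())
    keep = np.flatnonzero(counts * voxel_volume >= min_mm3)
    keep = keep[keep > 0]
    return np.isin(labelled, keep)


def _fill_enclosed(slice_mask: np.ndarray, max_area_px: float) -> np.ndarray:
    """Fill background regions of area < max_area_px completely surrounded by
    the foreground within one axial slice."""
    out = slice_mask.copy()
    background = ~slice_mask
    labelled, n = ndimage.label(background)  # 4-connectivity for the complement
    for comp in range(1, n + 1):
        region = labelled == comp
        if region.sum() >= max_area_px:
            continue
        idx = np.argwhere(region)
        if (idx.min() == 0 or idx[:, 0].max() == slice_mask.shape[0] - 1
                or idx[:, 1].max() == slice_mask.shape[1] - 1):
            continue  # touches the slice border: not enclosed
        ring = ndimage.binary_dilation(region, structure=np.ones((3, 3), bool)) & ~region
        if np.all(slice_mask[ring]):
            out |= region
    return out


def morph_refine(abt_mask: np.ndarray, voxel_size: tuple[float, ...],
                 min_component_mm3: float = 3.0, closing_radius_px: int = 2,
                 fill_hole_mm2: float = 16.0,
                 voi: np.ndarray | None = None) -> np.ndarray:
    """Morphological polish of the grown ABT object.

    (1) remove 3-D components below ``min_component_mm3``; (2) slice-wise
    closing with a disc of ``closing_radius_px`` pixels; (3) slice-wise fill
    of enclosed non-ABT regions below ``fill_hole_mm2``.  The result is
    clipped to the VOI when one is given.
    """
    mask = remove_small_components(abt_mask, voxel_size, min_component_mm3)
    footprint = disk(closing_radius_px)
    pixel_area = float(voxel_size[0] * voxel_size[1])
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        sl = closing(mask[:, :, k], footprint)
        out[:, :, k] = _fill_enclosed(sl, fill_hole_mm2 / pixel_area)
    if voi is not None:
        out &= voi.astype(bool)
    return out


def subdivide_final_abt(abt_mask: np.ndarray, dwi_volume: np.ndarray) -> np.ndarray:
    """Split the final ABT into DWI-hyperintense vs iso-/normointense objects."""
    return split_lesion_by_dwi(abt_mask, dwi_volume)


# -- orchestration ----------------------------------------------------------

def segment_study(study: MultimodalStudy, templates: TemplateSet,
                  config: PipelineConfig | None = None) -> SegmentationResult:
    """Full segmentation: z-score, outliers, DWI split, PCA, EM, posterior
    labelling, region growing, morphology and final DWI subdivision.

    If the outlier stage finds too few candidate voxels to estimate two lesion
    classes, the study is reported lesion-free (empty ABT) rather than failing:
    on such scans the mixture has nothing abnormal to model.
    """
    cfg = config or PipelineConfig()
    study.require("T1w", "DWI", "FLAIR")
    if study.voi is not None:
        voi = study.voi.astype(bool)
    elif study.class_probabilities is not None:
        voi = make_voi_mask(study.class_probabilities, cfg.voi_probability_threshold).mask
    else:
        raise ValueError("study needs a VOI or class probability maps")

    log: dict = {"stages": []}

    def _stage(name, **params):
        log["stages"].append({"stage": name, **params})

    try:
        zvols = {}
        for m in ("T1w", "DWI", "FLAIR"):
            lam = cfg.flair_trim_fraction if m == "FLAIR" else 0.0
            zvols[m] = zscore_image(study.modalities[m], voi, trim_fraction=lam)
        _stage("zscore", flair_trim=cfg.flair_trim_fraction)

        distances = {m: mahalanobis_distance(zvols[m], templates, m)
                     for m in ("T1w", "DWI", "FLAIR")}
        lesion0 = initial_lesion(distances, voi, cfg.mahalanobis_threshold)
        _stage("outliers", threshold=cfg.mahalanobis_threshold,
               n_initial_lesion=int(lesion0.sum()))

        # initial five-class labelling: tissue priors + DWI-split lesion
        labels0 = np.zeros(study.shape, dtype=np.int16)
        probs = study.class_probabilities
        if probs is None:
            raise ValueError("class probability maps are required for initial labels")
        stack = np.stack([probs["GM"], probs["WM"], probs["CSF"]])
        labels0[voi] = np.argmax(stack, axis=0)[voi] + 1
        lesion_split = split_lesion_by_dwi(lesion0, study.modalities["DWI"])
        labels0[lesion0] = lesion_split[lesion0]

        X = np.column_stack([zvols[m].values[voi] for m in ("T1w", "DWI", "FLAIR")])
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        scores = pca_reduce(X, cfg.pca_variance_threshold)
        M = scores.shape[1]
        _stage("pca", n_components=M)

        init = labels0[voi] - 1  # 0..4
        class_counts = np.bincount(init, minlength=5)
        if class_counts[3] < M + 1 or class_counts[4] < M + 1:
            logger.info("too few outlier voxels to model lesion classes "
                        "(counts %s); reporting study lesion-free", class_counts[3:])
            empty = np.zeros(study.shape, dtype=bool)
            gamma = np.zeros((int(voi.sum()), 5))
            gamma[np.arange(init.size), init] = 1.0
            _stage("em", skipped="insufficient lesion voxels")
            return SegmentationResult(labels=labels0, posteriors=gamma, voi=voi,
                                      abt_mask=empty,
                                      abt_subdivision=np.zeros(study.shape, np.int16),
                                      initial_lesion=lesion0, log=log)

        state = em_gmm(scores, init, K=5, tol=cfg.em_tol, max_iter=cfg.em_max_iter,
                       covariance_floor=cfg.em_covariance_floor)
        _stage("em", n_iter=state.n_iter, converged=state.converged)

        labels = np.zeros(study.shape, dtype=np.int16)
        labels[voi] = map_labels(state.gamma).astype(np.int16) + 1
        gamma_vol = np.zeros(study.shape + (5,))
        gamma_vol[voi] = state.gamma

        labels = region_grow_abt(labels, gamma_vol, voi,
                                 cfg.grow_margin, cfg.grow_sum_threshold)
        _stage("region_grow", margin=cfg.grow_margin,
               sum_threshold=cfg.grow_sum_threshold)

        abt = np.isin(labels, (Tissue.ABT_HYPER, Tissue.ABT_ISO))
        abt = morph_refine(abt, study.voxel_size, cfg.min_component_mm3,
                           cfg.closing_radius_px, cfg.fill_hole_mm2, voi=voi)
        _stage("morphology", min_mm3=cfg.min_component_mm3,
               closing_px=cfg.closing_radius_px, fill_mm2=cfg.fill_hole_mm2)

        subdivision = subdivide_final_abt(abt, study.modalities["DWI"])
        # voxels the morphology removed from ABT fall back to their best normal class
        dropped = voi & ~abt & np.isin(labels, (Tissue.ABT_HYPER, Tissue.ABT_ISO))
        labels[dropped] = np.argmax(gamma_vol[dropped][:, :3], axis=1) + 1
        labels[abt] = subdivision[abt]
        return SegmentationResult(labels=labels, posteriors=state.gamma, voi=voi,
                                  abt_mask=abt, abt_subdivision=subdivision,
                                  initial_lesion=lesion0, log=log)
    except Exception as err:
        stage = log["stages"][-1]["stage"] if log["stages"] else "setup"
        raise RuntimeError(f"segmentation failed after stage {stage!r}: {err}") from err
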