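"""Synthetic data generators: head phantoms, control cohorts, contrast pairs,
clinical cohort tables and ECoG event streams.

Every generator is deterministic given its spec and seed.  A master seed
spawns per-subject and per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn(...)``, so adding subjects never
perturbs earlier ones.

The phantom head is an ellipsoid with a CSF rim, a GM shell and a WM core,
plus a central ventricular CSF space.  That is deliberately simple: the
pipeline depends on class intensity statistics and spatial adjacency, not on
anatomy.  Reference regions for contrast calibration (vitreous body, temporal
muscle, venous-sinus blood) are placed as small spheres outside the brain
ellipsoid, mirroring where they are drawn on real scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bbbd import gaussian_intersection_params
from .types import GroundTruth, MultimodalStudy, Tissue

logger = logging.getLogger(__name__)

# -- phantom geometry / intensity defaults ---------------------------------

DEFAULT_GRID = (64, 64, 24)
DEFAULT_VOXEL = (2.0, 2.0, 5.0)            # mm; thick-slice clinical protocol

#: per-modality mean intensity (arbitrary units) per tissue class
DEFAULT_CLASS_MEANS: dict[str, dict[Tissue, float]] = {
    "T1w": {Tissue.GM: 60.0, Tissue.WM: 80.0, Tissue.CSF: 30.0,
            Tissue.ABT_HYPER: 55.0, Tissue.ABT_ISO: 55.0},
    "DWI": {Tissue.GM: 50.0, Tissue.WM: 45.0, Tissue.CSF: 20.0,
            Tissue.ABT_HYPER: 90.0, Tissue.ABT_ISO: 45.0},
    "FLAIR": {Tissue.GM: 55.0, Tissue.WM: 45.0, Tissue.CSF: 15.0,
              Tissue.ABT_HYPER: 85.0, Tissue.ABT_ISO: 85.0},
}

DEFAULT_CLASS_SDS: dict[str, float] = {"T1w": 3.0, "DWI": 3.0, "FLAIR": 3.0}

#: reference-ROI placement: centre mm, radius mm, pre-contrast intensity,
#: enhancement mean, enhancement SD.  Enhancement means must be ordered
#: vitreous < muscle < vessel.
DEFAULT_ROI_SPECS: dict[str, dict] = {
    "vitreous": {"centre": (14.0, 14.0, 60.0), "radius": 7.0,
                 "intensity": 30.0, "enh_mean": 0.02, "enh_sd": 0.01},
    "muscle": {"centre": (14.0, 114.0, 60.0), "radius": 7.0,
               "intensity": 70.0, "enh_mean": 0.15, "enh_sd": 0.03},
    "vessel": {"centre": (114.0, 114.0, 60.0), "radius": 7.0,
               "intensity": 80.0, "enh_mean": 0.60, "enh_sd": 0.08},
}

_HEAD_SEMIAXES = (55.0, 58.0, 52.0)        # mm
_WM_FRACTION = 0.62                        # normalised radius of WM core
_GM_FRACTION = 0.90                        # GM shell outer bound; CSF rim beyond
_VENTRICLE_SEMIAXES = (14.0, 18.0, 10.0)   # central CSF space


def analytic_thresholds(roi_specs: dict[str, dict] | None = None) -> tuple[float, float]:
    """Exact tau1/tau2 from the generating ROI enhancement Gaussians."""
    rs = roi_specs or DEFAULT_ROI_SPECS
    tau1 = gaussian_intersection_params(rs["vitreous"]["enh_mean"], rs["vitreous"]["enh_sd"],
                                        rs["muscle"]["enh_mean"], rs["muscle"]["enh_sd"])
    tau2 = gaussian_intersection_params(rs["muscle"]["enh_mean"], rs["muscle"]["enh_sd"],
                                        rs["vessel"]["enh_mean"], rs["vessel"]["enh_sd"])
    return tau1, tau2


def _default_lesions() -> list[tuple]:
    return [((40.0, 64.0, 60.0), (10.0, 10.0, 10.0), Tissue.ABT_HYPER)]


def _default_bbbd() -> list[tuple]:
    tau1, tau2 = analytic_thresholds()
    return [((44.0, 70.0, 60.0), (8.0, 8.0, 8.0), 0.5 * (tau1 + tau2))]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic multimodal head study.

    ``lesion_blobs`` are ``(centre_mm, radii_mm, tissue_class)`` ellipsoids;
    ``bbbd_blobs`` are ``(centre_mm, radii_mm, leakage_amplitude)``.  The
    default lesion is a single 10-mm-radius DWI-hyperintense blob and the
    default leakage amplitude sits midway between the analytic tau1 and tau2
    of the default reference ROIs.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL
    class_means: dict[str, dict[Tissue, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CLASS_MEANS.items()})
    class_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SDS))
    lesion_blobs: list[tuple] = field(default_factory=_default_lesions)
    bbbd_blobs: list[tuple] = field(default_factory=_default_bbbd)
    roi_specs: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROI_SPECS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in self.class_sds.values():
            if sd < 0:
                raise ValueError("class noise SDs must be >= 0")
        for name in ("vitreous", "muscle", "vessel"):
            if name not in self.roi_specs:
                raise ValueError(f"roi_specs must define {name!r}")
            if self.roi_specs[name]["enh_sd"] <= 0 or self.roi_specs[name]["radius"] <= 0:
                raise ValueError("ROI radius and enhancement SD must be > 0")
        means = [self.roi_specs[n]["enh_mean"] for n in ("vitreous", "muscle", "vessel")]
        if not (means[0] < means[1] < means[2]):
            raise ValueError("ROI enhancement means must be ordered vitreous < muscle < vessel")
        for centre, radii, _ in list(self.lesion_blobs) + list(self.bbbd_blobs):
            radii = np.broadcast_to(np.asarray(radii, float), (3,))
            if np.any(radii <= 0):
                raise ValueError("blob radii must be > 0")
            if not self._inside_head(np.asarray(centre, float), radii):
                raise ValueError(f"blob at {centre} does not lie inside the head ellipsoid")

    # -- geometry helpers --------------------------------------------------

    def _grid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [(np.arange(n) + 0.5) * s for n, s in zip(self.grid_shape, self.voxel_size)]
        return np.meshgrid(*axes, indexing="ij")

    @property
    def head_centre(self) -> np.ndarray:
        return 0.5 * np.asarray(self.grid_shape, float) * np.asarray(self.voxel_size, float)

    def _inside_head(self, centre: np.ndarray, radii: np.ndarray) -> bool:
        # conservative: blob fits if the inflated normalised radius stays <= 1
        rel = (centre - self.head_centre) / np.asarray(_HEAD_SEMIAXES)
        margin = float(np.max(radii / np.asarray(_HEAD_SEMIAXES)))
        return float(np.sqrt(np.sum(rel**2))) + margin <= 1.0

    def _ellipsoid_mask(self, centre, radii) -> np.ndarray:
        xs, ys, zs = self._grid_mm()
        centre = np.asarray(centre, float)
        radii = np.broadcast_to(np.asarray(radii, float), (3,))
        r2 = ((xs - centre[0]) / radii[0]) ** 2 + ((ys - centre[1]) / radii[1]) ** 2 \
            + ((zs - centre[2]) / radii[2]) ** 2
        return r2 <= 1.0

    def anatomy_labels(self) -> np.ndarray:
        """Lesion-free tissue labels: CSF rim, GM shell, WM core, ventricles."""
        xs, ys, zs = self._grid_mm()
        c = self.head_centre
        a = np.asarray(_HEAD_SEMIAXES)
        rnorm = np.sqrt(((xs - c[0]) / a[0]) ** 2 + ((ys - c[1]) / a[1]) ** 2
                        + ((zs - c[2]) / a[2]) ** 2)
        labels = np.full(self.grid_shape, Tissue.BACKGROUND, dtype=np.int16)
        labels[rnorm <= 1.0] = Tissue.CSF
        labels[rnorm <= _GM_FRACTION] = Tissue.GM
        labels[rnorm <= _WM_FRACTION] = Tissue.WM
        labels[self._ellipsoid_mask(c, _VENTRICLE_SEMIAXES)] = Tissue.CSF
        return labels


# -- study generation -------------------------------------------------------

def _render_study(spec: PhantomSpec, labels: np.ndarray,
                  rng: np.random.Generator, subject_id: str) -> MultimodalStudy:
    """Mean intensity per class plus additive Gaussian noise, per modality."""
    modalities: dict[str, np.ndarray] = {}
    for m, means in spec.class_means.items():
        vol = np.zeros(spec.grid_shape, dtype=np.float64)
        for cls, mu in means.items():
            vol[labels == cls] = mu
        # reference ROIs carry a base intensity so relative enhancement is defined
        if m == "T1w":
            for roi in spec.roi_specs.values():
                vol[spec._ellipsoid_mask(roi["centre"], roi["radius"])] = roi["intensity"]
        sd = spec.class_sds.get(m, 0.0)
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, size=spec.grid_shape)
        vol[vol < 0] = 0.0
        modalities[m] = vol
    probs = {name: (labels == cls).astype(np.float64)
             for name, cls in (("GM", Tissue.GM), ("WM", Tissue.WM), ("CSF", Tissue.CSF))}
    return MultimodalStudy(modalities=modalities, voxel_size=spec.voxel_size,
                           class_probabilities=probs, subject_id=subject_id)


def generate_control_cohort(spec: PhantomSpec, n_controls: int = 21) -> list[MultimodalStudy]:
    """Lesion-free studies sharing the spec's geometry.

    The default of 21 subjects matches the healthy reference cohort size the
    templates are meant to emulate.  Per-subject noise is independent, driven
    by child seeds spawned from ``spec.seed``.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls: template variance is undefined otherwise")
    labels = spec.anatomy_labels()
    children = np.random.SeedSequence(spec.seed).spawn(n_controls)
    return [_render_study(spec, labels, np.random.default_rng(child), f"control-{i:03d}")
            for i, child in enumerate(children)]


def generate_patient_study(spec: PhantomSpec) -> tuple[MultimodalStudy, GroundTruth]:
    """One lesioned study plus its ground truth.

    Lesion blobs overwrite the underlying anatomy; when blobs of different
    class overlap, the later blob wins (a warning is logged).  DWI-hyperintense
    blobs receive an elevated DWI mean, iso blobs do not; FLAIR is elevated in
    all lesion voxels (see the class-mean table).
    """
    labels = spec.anatomy_labels()
    head = labels != Tissue.BACKGROUND
    overlap_seen = False
    lesion_so_far = np.zeros(spec.grid_shape, dtype=bool)
    for centre, radii, cls in spec.lesion_blobs:
        blob = spec._ellipsoid_mask(centre, radii) & head
        if np.any(blob & lesion_so_far):
            overlap_seen = True
        labels[blob] = int(cls)
        lesion_so_far |= blob
    if overlap_seen:
        logger.warning("overlapping lesion blobs: later blob wins where they intersect")

    seq = np.random.SeedSequence(spec.seed).spawn(2)
    rng_img, rng_enh = (np.random.default_rng(s) for s in seq)
    study = _render_study(spec, labels, rng_img, "patient-000")
    study.voi = head.copy()

    enhancement = np.zeros(spec.grid_shape, dtype=np.float64)
    bbbd_mask = np.zeros(spec.grid_shape, dtype=bool)
    for centre, radii, amplitude in spec.bbbd_blobs:
        blob = spec._ellipsoid_mask(centre, radii) & head
        enhancement[blob] = float(amplitude)
        bbbd_mask |= blob
    roi_masks = {}
    for name, roi in spec.roi_specs.items():
        mask = spec._ellipsoid_mask(roi["centre"], roi["radius"])
        enhancement[mask] = rng_enh.normal(roi["enh_mean"], roi["enh_sd"], int(mask.sum()))
        roi_masks[name] = mask
    truth = GroundTruth(label_volume=labels, bbbd_mask=bbbd_mask,
                        enhancement_truth=enhancement, roi_masks=roi_masks)
    return study, truth


def simulate_contrast_pair(study: MultimodalStudy, truth: GroundTruth,
                           noise_sd: float = 1.0, seed: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Pre/post gadolinium T1w pair: ``post = pre * (1 + truth) + noise``.

    With ``noise_sd`` 0 the pair inverts exactly to the true enhancement
    field.  Negative post intensities (possible at high noise) are clipped to
    zero with a warning.
    """
    study.require("T1w")
    pre = study.modalities["T1w"]
    post = pre * (1.0 + truth.enhancement_truth)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed if seed is not None else 0))
        post = post + rng.normal(0.0, noise_sd, size=pre.shape)
    if np.any(post < 0):
        warnings.warn("negative post-contrast intensities clipped to 0", stacklevel=2)
        post = np.clip(post, 0.0, None)
    return pre.copy(), post


# -- clinical cohort tables --------------------------------------------------

PREDICTOR_NAMES = (
    "WFNS", "RMS",
    "NBT_iBBB_pct_early", "ABT_iBBB_pct_early",
    "NBT_BBBD_pct_early", "ABT_BBBD_pct_early",
    "PTSDD", "peak_seizure", "PTDDD", "peak_SD",
    "MRS_Day14",
    "NBT_iBBB_pct_postmon", "ABT_iBBB_pct_postmon",
    "NBT_BBBD_pct_postmon", "ABT_BBBD_pct_postmon",
)

#: distribution family and parameters per predictor; families:
#: randint(lo, hi) inclusive, gamma(shape, scale), zgamma(p_zero, shape, scale)
DEFAULT_PREDICTOR_DISTRIBUTIONS: dict[str, tuple] = {
    "WFNS": ("randint", 1, 5),
    "RMS": ("randint", 2, 9),
    "NBT_iBBB_pct_early": ("gamma", 80.0, 1.0),
    "ABT_iBBB_pct_early": ("gamma", 2.0, 2.0),
    "NBT_BBBD_pct_early": ("gamma", 2.0, 1.0),
    "ABT_BBBD_pct_early": ("gamma", 1.5, 0.8),
    "PTSDD": ("zgamma", 0.9, 1.5, 10.0),
    "peak_seizure": ("zgamma", 0.9, 1.0, 2.0),
    "PTDDD": ("gamma", 1.2, 150.0),
    "peak_SD": ("gamma", 1.5, 7.0),
    "MRS_Day14": ("randint", 0, 6),
    "NBT_iBBB_pct_postmon": ("gamma", 75.0, 1.0),
    "ABT_iBBB_pct_postmon": ("gamma", 2.5, 2.0),
    "NBT_BBBD_pct_postmon": ("gamma", 2.5, 1.2),
    "ABT_BBBD_pct_postmon": ("gamma", 1.8, 1.0),
}

#: logistic outcome model on the predictor scale.  The only nonzero slope is
#: on ABT_BBBD_pct_postmon (0.737 per percentage point), the study's headline
#: predictor; the intercept sets a ~40% marginal event rate.
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, float] = {
    "intercept": -1.8, "ABT_BBBD_pct_postmon": 0.737,
}

#: marginal MAR missingness per variable (WFNS/RMS complete by design)
DEFAULT_MISSINGNESS_RATES: dict[str, float] = {
    **{n: 0.0 for n in PREDICTOR_NAMES},
    "NBT_iBBB_pct_early": 0.12, "ABT_iBBB_pct_early": 0.12,
    "NBT_BBBD_pct_early": 0.12, "ABT_BBBD_pct_early": 0.12,
    "PTSDD": 0.03, "peak_seizure": 0.03, "PTDDD": 0.03, "peak_SD": 0.03,
    "MRS_Day14": 0.04,
    "NBT_iBBB_pct_postmon": 0.05, "ABT_iBBB_pct_postmon": 0.05,
    "NBT_BBBD_pct_postmon": 0.05, "ABT_BBBD_pct_postmon": 0.05,
}


@dataclass
class CohortSpec:
    """Generator spec for a synthetic prognostic cohort."""

    n_patients: int = 121
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    predictor_distributions: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_DISTRIBUTIONS))
    outcome_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS))
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.predictor_names) != 15:
            raise ValueError("the predictor panel has exactly 15 variables")
        for v in ("WFNS", "RMS"):
            if self.missingness_rates.get(v, 0.0) != 0.0:
                raise ValueError(f"{v} must be complete (MAR conditioning variable)")
        for name, rate in self.missingness_rates.items():
            if rate >= 1.0:
                raise ValueError(f"missingness rate for {name} must be < 1")


def _draw_predictor(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    family = dist[0]
    if family == "randint":
        return rng.integers(dist[1], dist[2] + 1, size=n).astype(float)
    if family == "gamma":
        return rng.gamma(dist[1], dist[2], size=n)
    if family == "zgamma":
        vals = rng.gamma(dist[2], dist[3], size=n)
        vals[rng.random(n) < dist[1]] = 0.0
        return vals
    if family == "normal":
        return rng.normal(dist[1], dist[2], size=n)
    raise ValueError(f"unknown predictor distribution family {family!r}")


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Predictors, Bernoulli outcomes from the logistic model, MAR missingness.

    Missingness is applied to the predictor columns conditional on the
    complete WFNS and RMS scores: a patient's per-variable missingness
    probability is the marginal rate tilted multiplicatively by
    ``exp(0.4 * (z_WFNS + z_RMS))`` and renormalised, so sicker patients lose
    more data (as in real neurocritical-care cohorts).  The generating
    coefficients are kept in ``df.attrs['outcome_coefficients']`` and the
    pre-missingness table in ``df.attrs['complete']``.
    """
    seq = np.random.SeedSequence(spec.seed).spawn(3)
    rng_x, rng_y, rng_miss = (np.random.default_rng(s) for s in seq)
    n = spec.n_patients
    data = {name: _draw_predictor(spec.predictor_distributions[name], n, rng_x)
            for name in spec.predictor_names}
    df = pd.DataFrame(data)

    eta = np.full(n, spec.outcome_coefficients.get("intercept", 0.0))
    for name, beta in spec.outcome_coefficients.items():
        if name != "intercept":
            eta = eta + beta * df[name].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta))
    if np.any((prob <= 0) | (prob >= 1)):
        raise ValueError("outcome probabilities must lie strictly in (0, 1)")
    df["outcome"] = rng_y.random(n) < prob

    complete = df.copy()
    tilt = np.exp(0.4 * (_standardise(df["WFNS"]) + _standardise(df["RMS"])))
    tilt = tilt / tilt.mean()
    for name, rate in spec.missingness_rates.items():
        if rate <= 0:
            continue
        p = np.clip(rate * tilt, 0.0, 0.95)
        df.loc[rng_miss.random(n) < p, name] = np.nan
    df["outcome"] = df["outcome"].astype(int)
    complete["outcome"] = complete["outcome"].astype(int)
    df.attrs["outcome_coefficients"] = dict(spec.outcome_coefficients)
    df.attrs["event_probability"] = prob
    df.attrs["complete"] = complete
    return df


def generating_model_auc(spec: CohortSpec, n_mc: int = 200_000, seed: int = 12345) -> float:
    """Monte-Carlo AUC of the generating logistic model itself.

    Draws a large cohort from the spec (no missingness), computes the true
    linear predictor per subject and the Bernoulli outcome, and returns the
    probability that a random case outranks a random control — the best AUC
    any model on these predictors can attain in expectation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eta = np.full(n_mc, spec.outcome_coefficients.get("intercept", 0.0))
    for name, beta in spec.outcome_coefficients.items():
        if name != "intercept":
            eta = eta + beta * _draw_predictor(
                spec.predictor_distributions[name], n_mc, rng)
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = rng.random(n_mc) < prob
    if y.all() or not y.any():
        raise ValueError("degenerate outcome model")
    from scipy.stats import rankdata

    ranks = rankdata(eta)
    n1 = int(y.sum())
    n0 = n_mc - n1
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _standardise(s: pd.Series) -> np.ndarray:
    x = s.to_numpy(dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# -- ECoG event streams ------------------------------------------------------

def generate_ecog_events(n_days: int, sd_rate_per_day: float = 4.0,
                         seizure_rate_per_day: float = 0.2,
                         seed: int = 0) -> pd.DataFrame:
    """Poisson event streams of spreading depolarisations and seizures.

    Default rates approximate a monitored haemorrhage patient: about four
    depolarisations per recording day and rare electrographic seizures.
    SD rows carry the depression duration (minutes, gamma with mean 15);
    seizure durations are 10 s plus an exponential tail, honouring the
    10-second definitional minimum.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if sd_rate_per_day < 0 or seizure_rate_per_day < 0:
        raise ValueError("event rates must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[tuple] = []
    for day in range(n_days):
        for _ in range(rng.poisson(sd_rate_per_day)):
            onset = (day + rng.random()) * 24.0
            rows.append(("SD", onset, float(rng.gamma(2.0, 7.5))))
        for _ in range(rng.poisson(seizure_rate_per_day)):
            onset = (day + rng.random()) * 24.0
            dur_min = 10.0 / 60.0 + float(rng.exponential(0.8))
            rows.append(("seizure", onset, dur_min))
    df = pd.DataFrame(rows, columns=["kind", "onset_hours", "duration_min"])
    return df.sort_values("onset_hours", kind="stable").reset_index(drop=True)
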