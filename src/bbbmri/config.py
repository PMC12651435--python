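"""Pipeline configuration.

Defaults reproduce the method's published constants: Mahalanobis outlier
threshold 3, FLAIR trim fraction 3%, PCA retention 5% of variance,
region-growing margins 0.1 / 0.5, morphology 3 mm^3 / 2 px / 16 mm^2,
BBBD cluster minimum 4 voxels, expansion band 0.5*tau1 - 1.5*tau2,
vicinity rings at 1 / 2 / 3 cm, 500 imputation samples and forward-selection
thresholds 0.05 / 0.10.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    # preprocessing
    voi_probability_threshold: float = 0.5
    flair_trim_fraction: float = 0.03     # lambda, patient FLAIR only
    template_variance_floor: float = 1e-6

    # segmentation
    mahalanobis_threshold: float = 3.0
    pca_variance_threshold: float = 0.05
    em_tol: float = 1e-6
    em_max_iter: int = 100
    em_covariance_floor: float = 1e-6
    grow_margin: float = 0.1              # posterior-gap inclusion margin
    grow_sum_threshold: float = 0.5       # gamma4 + gamma5 inclusion bound
    min_component_mm3: float = 3.0
    closing_radius_px: int = 2
    fill_hole_mm2: float = 16.0
    slice_connectivity_8: bool = True     # 2-D 8-connectivity within axial slices

    # BBBD mapping
    bbbd_min_cluster_voxels: int = 4
    bbbd_expand_low: float = 0.5          # multiples of tau1
    bbbd_expand_high: float = 1.5         # multiples of tau2
    bbbd_connectivity_3d: bool = False    # slice-wise 8-connectivity by default

    # vicinity analysis
    ring_bounds_mm: tuple[float, ...] = (10.0, 20.0, 30.0)

    # prognostics
    n_imputations: int = 500
    p_inclusion: float = 0.05
    p_exclusion: float = 0.10
    bonferroni_m: int = 15
    auc_ci_method: str = "delong"         # or "hanley-mcneil"

    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if "ring_bounds_mm" in data:
            data["ring_bounds_mm"] = tuple(data["ring_bounds_mm"])
        return cls(**data)
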