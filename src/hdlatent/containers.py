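"""Shared in-memory containers for the imaging pipeline.

All image grids are numpy arrays indexed (x, y, z) with a common voxel
spacing in mm per axis.  Hounsfield units (HU) are used for raw CT
attenuation; the two-channel representation stores rescaled density in
[0, 1] and the registration Jacobian determinant J (EX/IN local volume
ratio, dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOBE_LABELS = ("LUL", "LLL", "RUL", "RML", "RLL")


@dataclass
class TissuePatternSpec:
    """Statistical description of one synthetic tissue-pattern class.

    ``mean_hu``/``sd_hu`` describe CT attenuation at full inspiration;
    ``mean_j``/``sd_j`` the local EX/IN volume ratio (J < 1 means the
    region is larger at TLC than at RV, i.e. it deflates normally).
    ``blob_scale_mm`` sets the spatial coherence length of the pattern,
    on the order of a secondary pulmonary lobule (~20 mm).
    """

    name: str
    mean_hu: float
    sd_hu: float
    mean_j: float
    sd_j: float
    blob_scale_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.sd_hu < 0 or self.sd_j < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (-1024.0 <= self.mean_hu <= 200.0):
            raise ValueError("mean_hu must lie in [-1024, 200] HU")
        if self.mean_j <= 0:
            raise ValueError("mean_j must be positive")


@dataclass
class SubjectProfile:
    """Per-subject ground truth and clinical covariates."""

    subject_id: str
    group_id: str
    pattern_mixture: dict[str, float]
    exposure: int = 0
    gender: int = 0          # 0 = female, 1 = male
    age: float = 50.0
    height: float = 165.0    # cm
    weight: float = 65.0     # kg
    fvc_pct: float = 90.0
    fev1_pct: float = 93.0

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.pattern_mixture.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("pattern_mixture entries must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("pattern_mixture must sum to 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class PairedLungScan:
    """Paired inspiratory/expiratory CT record on the IN grid.

    ``ex_volume`` is the registered expiratory image resampled to the IN
    frame.  ``displacement`` maps IN coordinates to EX coordinates in mm
    (shape ``shape + (3,)``).
    """

    in_volume: np.ndarray
    ex_volume: np.ndarray
    lung_mask: np.ndarray
    lobe_mask: np.ndarray
    displacement: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""
    pattern_label: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shape = self.in_volume.shape
        for name in ("ex_volume", "lung_mask", "lobe_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if self.displacement.shape != shape + (3,):
            raise ValueError("displacement must have shape grid + (3,)")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing must be positive")
        if np.any((self.lobe_mask > 0) & ~self.lung_mask.astype(bool)):
            raise ValueError("lobe_mask must be contained in lung_mask")


@dataclass
class TwoChannelVolume:
    """Co-located rescaled density and Jacobian channels on the IN grid."""

    density: np.ndarray
    jacobian: np.ndarray
    lung_mask: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (self.density.shape == self.jacobian.shape == self.lung_mask.shape):
            raise ValueError("channel shapes must match")
        if self.density.min() < -1e-9 or self.density.max() > 1 + 1e-9:
            raise ValueError("density must lie in [0, 1]")
        inside = self.lung_mask.astype(bool)
        if inside.any() and self.jacobian[inside].min() <= 0:
            raise ValueError("jacobian must be positive inside the lung")

    def stacked(self) -> np.ndarray:
        """Return a (2, nx, ny, nz) array: channel 0 density, channel 1 J."""
        return np.stack([self.density, self.jacobian], axis=0)


@dataclass
class Patch:
    """A lobule-sized two-channel cube cut from a TwoChannelVolume."""

    data: np.ndarray            # (2, e, e, e)
    lung_mask: np.ndarray       # (e, e, e) bool
    center_mm: tuple[float, float, float]
    subject_id: str
    lung_fraction: float
    label: str | None = None    # ground-truth pattern label when synthetic
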