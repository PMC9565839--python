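"""Lobule-sized two-channel 3D patch extraction.

Random patches feed autoencoder training; a deterministic sliding-window
raster over the lung bounding box feeds whole-lung quantification.  The
default 20 mm cube matches the scale of a secondary pulmonary lobule.
Volumes are assumed isotropic (use :func:`resample_isotropic` first if
not).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import Patch, TwoChannelVolume

__all__ = [
    "sample_random_rois",
    "sliding_window_rois",
    "resample_isotropic",
    "patch_index_frame",
]

DEFAULT_ROI_MM = 20.0
DEFAULT_MIN_LUNG_FRACTION = 0.5
DEFAULT_STRIDE_MM = 10.0


def _edge_voxels(roi_mm: float, spacing: float) -> int:
    edge = int(round(roi_mm / spacing))
    if edge < 2:
        raise ValueError("ROI smaller than 2 voxels; check roi_mm/spacing")
    return edge


def _check_isotropic(volume: TwoChannelVolume) -> float:
    sp = np.asarray(volume.spacing, dtype=float)
    if not np.allclose(sp, sp[0], rtol=1e-3):
        raise ValueError("volume must be isotropic; resample_isotropic() first")
    return float(sp[0])


def _cut(volume: TwoChannelVolume, start: np.ndarray, edge: int, spacing: float,
         label_grid: np.ndarray | None) -> Patch:
    sl = tuple(slice(s, s + edge) for s in start)
    data = np.stack([volume.density[sl], volume.jacobian[sl]], axis=0)
    mask = volume.lung_mask[sl].astype(bool)
    center = (start + edge / 2.0) * spacing
    label = None
    if label_grid is not None and mask.any():
        vals, counts = np.unique(label_grid[sl][mask], return_counts=True)
        label = str(vals[np.argmax(counts)])
    return Patch(
        data=data,
        lung_mask=mask,
        center_mm=tuple(center),
        subject_id=volume.subject_id,
        lung_fraction=float(mask.mean()),
        label=label,
    )


def sample_random_rois(
    volume: TwoChannelVolume,
    n: int,
    roi_mm: float = DEFAULT_ROI_MM,
    min_lung_fraction: float = DEFAULT_MIN_LUNG_FRACTION,
    seed: int = 0,
    label_grid: np.ndarray | None = None,
    max_tries_per_patch: int = 200,
) -> list[Patch]:
    """Draw ``n`` patches with centers uniform over positions whose cube
    meets ``min_lung_fraction``, by seeded rejection sampling.

    ``label_grid`` (optional integer grid, e.g. the generator's pattern
    labels) attaches the majority in-lung label to each patch for
    ground-truth checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spacing = _check_isotropic(volume)
    edge = _edge_voxels(roi_mm, spacing)
    shape = np.asarray(volume.density.shape)
    if np.any(shape < edge):
        raise ValueError("volume smaller than one ROI")
    # precompute valid starts via a box-sum of the lung mask
    frac = ndimage.uniform_filter(volume.lung_mask.astype(float), size=edge)
    # uniform_filter is centered; convert to start-indexed validity
    off = edge // 2
    valid = frac[off:off + shape[0] - edge + 1,
                 off:off + shape[1] - edge + 1,
                 off:off + shape[2] - edge + 1] >= min_lung_fraction - 1e-9
    starts = np.argwhere(valid)
    if len(starts) == 0:
        raise ValueError(
            f"no patch position reaches lung fraction {min_lung_fraction}; "
            f"lung occupies {volume.lung_mask.mean():.1%} of the volume"
        )
    rng = np.random.default_rng(seed)
    picks = starts[rng.integers(0, len(starts), size=n)]
    return [_cut(volume, s, edge, spacing, label_grid) for s in picks]


def sliding_window_rois(
    volume: TwoChannelVolume,
    roi_mm: float = DEFAULT_ROI_MM,
    stride_mm: float = DEFAULT_STRIDE_MM,
    min_lung_fraction: float = DEFAULT_MIN_LUNG_FRACTION,
    label_grid: np.ndarray | None = None,
) -> list[Patch]:
    """Deterministic raster of patches over the lung bounding box;
    windows below ``min_lung_fraction`` are dropped."""
    if stride_mm <= 0:
        raise ValueError("stride_mm must be positive")
    spacing = _check_isotropic(volume)
    edge = _edge_voxels(roi_mm, spacing)
    stride = max(int(round(stride_mm / spacing)), 1)
    if not volume.lung_mask.any():
        warnings.warn("empty lung mask: no windows emitted")
        return []
    lo = np.array([idx.min() for idx in np.nonzero(volume.lung_mask)])
    hi = np.array([idx.max() for idx in np.nonzero(volume.lung_mask)]) + 1
    shape = np.asarray(volume.density.shape)
    starts_per_axis = []
    for a in range(3):
        s0 = max(lo[a] - edge // 2, 0)
        s_max = min(hi[a], shape[a] - edge)
        if s_max < s0:
            s0 = s_max = max(min(s0, shape[a] - edge), 0)
        starts_per_axis.append(np.arange(s0, s_max + 1, stride))
    out = []
    for sx in starts_per_axis[0]:
        for sy in starts_per_axis[1]:
            for sz in starts_per_axis[2]:
                p = _cut(volume, np.array([sx, sy, sz]), edge, spacing, label_grid)
                if p.lung_fraction >= min_lung_fraction - 1e-9:
                    out.append(p)
    if not out:
        warnings.warn("no window reached the lung-fraction threshold")
    return out


def resample_isotropic(volume: TwoChannelVolume, target_mm: float = 1.0) -> TwoChannelVolume:
    """Resample all channels to isotropic spacing (linear for channels,
    nearest for the mask)."""
    sp = np.asarray(volume.spacing, dtype=float)
    zoom = sp / target_mm
    if np.allclose(zoom, 1.0):
        return volume
    density = np.clip(ndimage.zoom(volume.density, zoom, order=1), 0.0, 1.0)
    jac = ndimage.zoom(volume.jacobian, zoom, order=1)
    mask = ndimage.zoom(volume.lung_mask.astype(np.uint8), zoom, order=0).astype(bool)
    jac = np.where(mask, np.maximum(jac, 1e-3), 1.0)
    density = np.where(mask, density, 0.0)
    return TwoChannelVolume(
        density=density, jacobian=jac, lung_mask=mask,
        spacing=(target_mm,) * 3, subject_id=volume.subject_id,
    )


def patch_index_frame(patches: list[Patch]) -> pd.DataFrame:
    """Index table (subject, center coordinates, lung fraction) for a
    persisted patch array."""
    return pd.DataFrame(
        [
            {
                "patch_id": i,
                "subject_id": p.subject_id,
                "cx_mm": p.center_mm[0],
                "cy_mm": p.center_mm[1],
                "cz_mm": p.center_mm[2],
                "lung_fraction": p.lung_fraction,
                "label": p.label,
            }
            for i, p in enumerate(patches)
        ]
    )
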