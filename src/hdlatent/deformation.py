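"""Jacobian determinant of a displacement field and two-channel assembly.

The displacement field u maps inspiratory (IN) coordinates to expiratory
(EX) coordinates in mm; the local volume change is det(I + grad u), the
EX-to-IN volume ratio J.  1/J is the local expansion from RV to TLC.
"""

from __future__ import annotations

import numpy as np

from .containers import PairedLungScan, TwoChannelVolume

#: density rescale window: air (-1024 HU) -> 0, soft tissue (200 HU) -> 1
HU_WINDOW = (-1024.0, 200.0)

#: positive floor applied to J before use as channel 2
J_FLOOR = 1e-3


def jacobian_determinant(
    displacement: np.ndarray,
    spacing: tuple[float, float, float] | float,
    floor: float | None = J_FLOOR,
) -> np.ndarray:
    """det(I + grad u) by central differences (one-sided at boundaries).

    Parameters
    ----------
    displacement:
        ``(nx, ny, nz, 3)`` array, mm, IN -> EX.
    spacing:
        Voxel spacing in mm (scalar or per-axis triple).
    floor:
        Positive clip applied to the result; ``None`` disables clipping.
    """
    u = np.asarray(displacement, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("displacement must have shape (nx, ny, nz, 3)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement contains non-finite values")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")

    # F[i][j] = d u_i / d x_j
    grad = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            grad[..., i, j] = np.gradient(u[..., i], sp[j], axis=j)
    grad[..., 0, 0] += 1.0
    grad[..., 1, 1] += 1.0
    grad[..., 2, 2] += 1.0
    det = np.linalg.det(grad)
    if floor is not None:
        det = np.maximum(det, floor)
    return det


def rescale_density(hu: np.ndarray) -> np.ndarray:
    """Linear map of HU in [-1024, 200] onto [0, 1], clamped outside."""
    lo, hi = HU_WINDOW
    return np.clip((np.asarray(hu, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def build_two_channel(scan: PairedLungScan, j_floor: float = J_FLOOR) -> TwoChannelVolume:
    """Assemble the two-channel volume: rescaled IN density + Jacobian.

    Outside-lung voxels are set to the neutral fill (density 0, J 1) so
    that patches overlapping the lung border carry no spurious signal.
    """
    if scan.displacement.shape[:3] != scan.in_volume.shape:
        raise ValueError("displacement grid does not match in_volume")
    density = rescale_density(scan.in_volume)
    jac = jacobian_determinant(scan.displacement, scan.spacing, floor=j_floor)
    inside = scan.lung_mask.astype(bool)
    density = np.where(inside, density, 0.0)
    jac = np.where(inside, jac, 1.0)
    return TwoChannelVolume(
        density=density,
        jacobian=jac,
        lung_mask=inside,
        spacing=tuple(np.broadcast_to(np.asarray(scan.spacing, float), (3,))),
        subject_id=scan.subject_id,
    )
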