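"""NIfTI persistence for scans, masks, displacement fields and
two-channel volumes (channel as the 4th axis)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import PairedLungScan, TwoChannelVolume

__all__ = ["save_scan", "load_scan", "save_two_channel", "load_two_channel"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _save(path: Path, data: np.ndarray, spacing) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(spacing)), str(path))


def save_scan(scan: PairedLungScan, directory: str | Path) -> dict[str, Path]:
    """Write one subject's volumes as uncompressed-friendly .nii.gz files;
    returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "in": d / "in_volume.nii.gz",
        "ex": d / "ex_volume.nii.gz",
        "lung": d / "lung_mask.nii.gz",
        "lobe": d / "lobe_mask.nii.gz",
        "displacement": d / "displacement.nii.gz",
    }
    _save(paths["in"], scan.in_volume.astype(np.float32), scan.spacing)
    _save(paths["ex"], scan.ex_volume.astype(np.float32), scan.spacing)
    _save(paths["lung"], scan.lung_mask.astype(np.uint8), scan.spacing)
    _save(paths["lobe"], scan.lobe_mask.astype(np.uint8), scan.spacing)
    _save(paths["displacement"], scan.displacement.astype(np.float32), scan.spacing)
    return paths


def load_scan(directory: str | Path, subject_id: str = "") -> PairedLungScan:
    d = Path(directory)

    def get(name):
        return np.asanyarray(nib.load(str(d / name)).dataobj)

    img = nib.load(str(d / "in_volume.nii.gz"))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return PairedLungScan(
        in_volume=get("in_volume.nii.gz").astype(float),
        ex_volume=get("ex_volume.nii.gz").astype(float),
        lung_mask=get("lung_mask.nii.gz").astype(bool),
        lobe_mask=get("lobe_mask.nii.gz").astype(np.int8),
        displacement=get("displacement.nii.gz").astype(float),
        spacing=spacing,
        subject_id=subject_id or d.name,
    )


def save_two_channel(volume: TwoChannelVolume, path: str | Path) -> None:
    data = np.stack([volume.density, volume.jacobian], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(volume.spacing)), str(path))


def load_two_channel(path: str | Path, lung_mask: np.ndarray | None = None,
                     subject_id: str = "") -> TwoChannelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4 or data.shape[-1] != 2:
        raise ValueError("expected a 4-D two-channel NIfTI")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    density, jac = data[..., 0], data[..., 1]
    if lung_mask is None:
        # density exactly 0 with J exactly 1 marks the outside fill
        lung_mask = ~((density == 0.0) & (jac == 1.0))
    return TwoChannelVolume(density=density, jacobian=jac,
                            lung_mask=lung_mask.astype(bool),
                            spacing=spacing, subject_id=subject_id)
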