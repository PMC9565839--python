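"""Quantitative CT metrics: LAA%, Tissue%, PRM-based fSAD%, RV/TLC and
airway-to-lung volume ratio, total and per lobe.

Thresholds follow field convention: emphysema-range low attenuation is
< -950 HU at TLC, gas trapping < -856 HU at RV; a voxel is functional
small-airway disease (fSAD) when it is non-emphysematous at TLC but
gas-trapping at RV (joint parametric-response-mapping rule).  Tissue
fraction interpolates linearly between air (-1000 HU) and soft tissue
(55 HU).  All thresholds are arguments with these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LOBE_LABELS, PairedLungScan

__all__ = [
    "laa_percent", "tissue_percent", "fsad_percent", "prm_percentages",
    "rv_tlc_ratio", "awv_percent", "QctRecord", "qct_record", "qct_table",
]

LAA_TLC_HU = -950.0
LAA_RV_HU = -856.0
HU_AIR = -1000.0
HU_TISSUE = 55.0


def laa_percent(volume: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Percentage of mask voxels below the attenuation threshold."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return 100.0 * float(np.mean(volume[mask] < threshold))


def tissue_percent(tlc_volume: np.ndarray, mask: np.ndarray,
                   hu_air: float = HU_AIR, hu_tissue: float = HU_TISSUE) -> float:
    """Mean fractional tissue content at TLC, from the linear HU mix of
    air and soft tissue."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    frac = np.clip((tlc_volume[mask] - hu_air) / (hu_tissue - hu_air), 0.0, 1.0)
    return 100.0 * float(frac.mean())


HAA_HU = -810.0     # high-attenuation (dense parenchyma) threshold at TLC


def fsad_percent(tlc: np.ndarray, rv_registered: np.ndarray, mask: np.ndarray,
                 tlc_threshold: float = LAA_TLC_HU, rv_threshold: float = LAA_RV_HU) -> float:
    """PRM functional small-airway disease percentage: TLC HU >= -950
    and registered-RV HU < -856 (non-emphysematous gas trapping)."""
    if tlc.shape != rv_registered.shape:
        raise ValueError("TLC and registered RV grids must share a frame")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    t = tlc[mask]
    r = rv_registered[mask]
    return 100.0 * float(np.mean((t >= tlc_threshold) & (r < rv_threshold)))


def prm_percentages(tlc: np.ndarray, rv_registered: np.ndarray, mask: np.ndarray,
                    tlc_threshold: float = LAA_TLC_HU,
                    rv_threshold: float = LAA_RV_HU,
                    haa_threshold: float = HAA_HU) -> dict[str, float]:
    """Four-class PRM decomposition, an exact partition of the mask:
    emphysema-like (low attenuation at both TLC and RV), fSAD (gas
    trapping without TLC emphysema), high-attenuation (dense parenchyma
    at TLC without trapping), and normal."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    t = tlc[mask]
    r = rv_registered[mask]
    trap = r < rv_threshold
    emph = trap & (t < tlc_threshold)
    fsad = trap & (t >= tlc_threshold)
    haa = ~trap & (t >= haa_threshold)
    normal = ~trap & (t < haa_threshold)
    return {
        "emphysema_pct": 100.0 * float(emph.mean()),
        "fsad_pct": 100.0 * float(fsad.mean()),
        "high_attenuation_pct": 100.0 * float(haa.mean()),
        "normal_pct": 100.0 * float(normal.mean()),
    }


def rv_tlc_ratio(rv_volume_ml: float, tlc_volume_ml: float) -> float:
    if rv_volume_ml <= 0 or tlc_volume_ml <= 0:
        raise ValueError("lung volumes must be positive")
    return rv_volume_ml / tlc_volume_ml


def awv_percent(airway_volume_ml: float, lung_volume_ml: float) -> float:
    if lung_volume_ml <= 0:
        raise ValueError("lung volume must be positive")
    if airway_volume_ml < 0:
        raise ValueError("airway volume must be non-negative")
    return 100.0 * airway_volume_ml / lung_volume_ml


@dataclass
class QctRecord:
    subject_id: str
    values: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def _region_masks(scan: PairedLungScan):
    yield "Total", scan.lung_mask.astype(bool)
    for i, lobe in enumerate(LOBE_LABELS, start=1):
        yield lobe, scan.lobe_mask == i


def qct_record(scan: PairedLungScan, jacobian: np.ndarray,
               airway_volume_ml: float | None = None) -> QctRecord:
    """All imaging metrics for one subject, total and per lobe.

    The registered-RV image lives on the TLC grid (the scan's EX
    convention), so the PRM rule applies voxelwise; RV lung volume is
    the Jacobian integral over the lung at TLC.
    """
    vals: dict[str, float] = {}
    voxel_ml = float(np.prod(scan.spacing)) / 1000.0
    for region, mask in _region_masks(scan):
        if not mask.any():
            continue
        vals[f"LAA_TLC_pct_{region}"] = laa_percent(scan.in_volume, mask, LAA_TLC_HU)
        vals[f"LAA_RV_pct_{region}"] = laa_percent(scan.ex_volume, mask, LAA_RV_HU)
        vals[f"Tissue_pct_{region}"] = tissue_percent(scan.in_volume, mask)
        vals[f"fSAD_pct_{region}"] = fsad_percent(scan.in_volume, scan.ex_volume, mask)
    lung = scan.lung_mask.astype(bool)
    tlc_ml = float(lung.sum()) * voxel_ml
    rv_ml = float(jacobian[lung].sum()) * voxel_ml
    vals["RV_TLC"] = rv_tlc_ratio(rv_ml, tlc_ml)
    vals["TLC_ml"] = tlc_ml
    vals["RV_ml"] = rv_ml
    if airway_volume_ml is not None:
        vals["AWV_pct"] = awv_percent(airway_volume_ml, tlc_ml)
    return QctRecord(scan.subject_id, vals)


def qct_table(records: list[QctRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_series() for r in records])
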