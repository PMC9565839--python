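"""Synthetic paired-CT cohort generator with known ground truth.

Every downstream stage (two-channel assembly, patch clustering, factor
analysis, subject clustering, airway surrogate) is exercised on data from
this module, so each generated quantity has a planted value the tests can
check against: per-voxel tissue-pattern labels, per-pattern attenuation
and Jacobian statistics, per-subject pattern mixtures, and group
membership.

The phantom is deliberately schematic: a pair of ellipsoidal "lungs"
split into five lobes by fixed fractional planes, with spatially coherent
pattern blobs obtained by quantile-partitioning a smoothed Gaussian
random field.  The displacement field is a purely axial (apex-base,
diaphragm-like) compression ``u = (0, 0, g)`` with
``g(x, y, z) = integral_0^z (j_target - 1) dz'``; for such a field
``det(I + grad u) = 1 + dg/dz = j_target`` exactly, independent of the
lateral variation of ``g``, and the map is invertible whenever
``j_target > 0``.  A short per-blob amplitude correction loop absorbs
the residual finite-difference smearing at blob faces so each blob's
mean Jacobian hits its planted ``mean_j``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, ndimage

from .airway import AirwayBranch, AirwayTree
from .containers import LOBE_LABELS, PairedLungScan, SubjectProfile, TissuePatternSpec

__all__ = [
    "DEFAULT_PATTERNS",
    "generate_subject",
    "generate_cohort",
    "generate_airway_tree",
]

#: Default tissue-pattern classes.  Densities/Jacobians are loosely
#: calibrated to the normalized attenuations (~0.09-0.27) and EX/IN
#: volume ratios (~0.44-1.47) that separate the latent traits observed
#: in humidifier-disinfectant cohorts: normal parenchyma, a hyperlucent
#: high-expansion pattern, a deflation-limited low-J pattern, and a
#: dense hypo-inflated pattern (J > 1: larger at RV than TLC).
DEFAULT_PATTERNS: dict[str, TissuePatternSpec] = {
    "normal": TissuePatternSpec("normal", mean_hu=-870.0, sd_hu=35.0, mean_j=0.55, sd_j=0.04),
    "hyperlucent": TissuePatternSpec("hyperlucent", mean_hu=-916.0, sd_hu=25.0, mean_j=0.77, sd_j=0.05),
    "low_j": TissuePatternSpec("low_j", mean_hu=-833.0, sd_hu=40.0, mean_j=0.44, sd_j=0.04),
    "hypoinflated": TissuePatternSpec("hypoinflated", mean_hu=-697.0, sd_hu=55.0, mean_j=1.40, sd_j=0.08),
}

_RIM_HU = 40.0      # soft-tissue shell around the lung
_AIR_HU = -1000.0


# ---------------------------------------------------------------------------
# lung phantom geometry
# ---------------------------------------------------------------------------

def _lung_and_lobe_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Two-ellipsoid lung mask plus a 5-label lobe mask.

    Left lung is split LUL/LLL at 45% height; right lung RUL/RML/RLL at
    fixed fractional planes (45%/20%/35% from the top).  z increases
    towards the apex.
    """
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    lobe = np.zeros(shape, dtype=np.int8)

    def ellipsoid(cx_frac):
        cx, cy, cz = cx_frac * nx, 0.5 * ny, 0.5 * nz
        ax, ay, az = 0.17 * nx, 0.30 * ny, 0.40 * nz
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    left = ellipsoid(0.30)
    right = ellipsoid(0.70)
    lung = left | right

    zf = z / max(nz - 1, 1)
    # labels: 1 LUL, 2 LLL, 3 RUL, 4 RML, 5 RLL
    lobe[left & (zf >= 0.55)] = 1
    lobe[left & (zf < 0.55)] = 2
    lobe[right & (zf >= 0.55)] = 3
    lobe[right & (zf >= 0.35) & (zf < 0.55)] = 4
    lobe[right & (zf < 0.35)] = 5
    return lung, lobe


def _smooth_unit_field(shape, sigma_vox, rng) -> np.ndarray:
    """Gaussian-smoothed white noise, rescaled to zero mean / unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    return (f - f.mean()) / f.std()


def _pattern_labels(
    lung: np.ndarray,
    patterns: list[TissuePatternSpec],
    mixture: np.ndarray,
    spacing: float,
    rng,
) -> np.ndarray:
    """Assign each lung voxel a pattern index by quantile-partitioning a
    smooth field: spatially coherent, disjoint blobs whose realized
    proportions match the mixture up to discretization."""
    scale_vox = float(np.mean([p.blob_scale_mm for p in patterns])) / spacing
    field = _smooth_unit_field(lung.shape, max(scale_vox / 2.0, 1.0), rng)
    inside = field[lung]
    # shuffle pattern order so the quantile bands are not always stacked
    # in dictionary order along the field's level sets
    order = rng.permutation(len(patterns))
    edges = np.concatenate([[0.0], np.cumsum(mixture[order])])
    edges[-1] = 1.0
    qs = np.quantile(inside, edges[1:-1]) if len(edges) > 2 else np.array([])
    band = np.searchsorted(qs, inside, side="right")
    labels = np.full(lung.shape, -1, dtype=np.int8)
    labels[lung] = order[band]
    return labels


# ---------------------------------------------------------------------------
# subject / cohort generation
# ---------------------------------------------------------------------------

def generate_subject(
    profile: SubjectProfile,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: float = 1.0,
    seed: int = 0,
    patterns: dict[str, TissuePatternSpec] | None = None,
    n_correction_iters: int = 3,
) -> PairedLungScan:
    """Generate one paired inspiratory/expiratory scan with known truth.

    The IN image realizes each pattern's (mean_hu, sd_hu) inside its
    blobs; the displacement field is constructed so the finite-difference
    Jacobian matches each blob's mean_j (axial compression whose
    z-derivative is the target, plus a per-blob amplitude correction);
    the EX image is the mass-conserving density rescale of IN by 1/J on
    the IN grid (registered-EX convention).
    """
    if min(shape) < 32:
        raise ValueError("each axis must be >= 32 voxels to host lobule-scale blobs")
    patterns = dict(patterns or DEFAULT_PATTERNS)
    missing = set(profile.pattern_mixture) - set(patterns)
    if missing:
        raise ValueError(f"mixture references undefined patterns: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    names = list(profile.pattern_mixture)
    specs = [patterns[n] for n in names]
    mixture = np.asarray([profile.pattern_mixture[n] for n in names], dtype=float)

    lung, lobe = _lung_and_lobe_masks(shape)
    labels = _pattern_labels(lung, specs, mixture, spacing, rng)

    mean_hu = np.array([s.mean_hu for s in specs])
    sd_hu = np.array([s.sd_hu for s in specs])
    texture = _smooth_unit_field(shape, 1.5, rng)
    in_vol = np.full(shape, _AIR_HU)
    rim = ndimage.binary_dilation(lung, iterations=3) & ~lung
    in_vol[rim] = _RIM_HU
    in_vol[lung] = mean_hu[labels[lung]] + sd_hu[labels[lung]] * texture[lung]
    in_vol = np.clip(in_vol, -1024.0, 200.0)

    # target Jacobian: per-blob mean_j with a smooth log-normal modulation
    mean_j = np.array([s.mean_j for s in specs])
    sd_j = np.array([s.sd_j for s in specs])
    rel = np.divide(sd_j, mean_j, out=np.zeros_like(sd_j), where=mean_j > 0)
    mod = _smooth_unit_field(shape, 4.0, rng) if rel.max() > 0 else np.zeros(shape)
    modulation = np.ones(shape)
    modulation[lung] = np.exp(rel[labels[lung]] * mod[lung])

    if np.allclose(mean_j, 1.0) and rel.max() == 0:
        disp = np.zeros(shape + (3,))
    else:
        disp = _axial_displacement(
            lung, labels, mean_j, modulation, spacing, n_correction_iters
        )

    jac = _finite_or_one(disp, spacing)
    ex_vol = in_vol.copy()
    ex_vol[lung] = np.clip(
        (in_vol[lung] + 1000.0) / np.maximum(jac[lung], 1e-3) - 1000.0, -1024.0, 200.0
    )

    return PairedLungScan(
        in_volume=in_vol,
        ex_volume=ex_vol,
        lung_mask=lung,
        lobe_mask=lobe,
        displacement=disp,
        spacing=(spacing,) * 3,
        subject_id=profile.subject_id,
        pattern_label=labels,
    )


def _finite_or_one(disp: np.ndarray, spacing: float) -> np.ndarray:
    from .deformation import jacobian_determinant

    if not disp.any():
        return np.ones(disp.shape[:3])
    return jacobian_determinant(disp, spacing)


def _axial_displacement(
    lung: np.ndarray,
    labels: np.ndarray,
    mean_j: np.ndarray,
    modulation: np.ndarray,
    spacing: float,
    n_iters: int,
) -> np.ndarray:
    """Axial compression field whose finite-difference Jacobian realizes
    the per-blob target: u_z = cumulative z-integral of (j - 1), with the
    target extended outside the lung by nearest neighbour and tapered by
    a smooth window; a few per-blob amplitude iterations absorb the
    central-difference smearing at blob boundaries."""
    from .deformation import jacobian_determinant

    shape = lung.shape
    nearest = ndimage.distance_transform_edt(
        ~lung, return_distances=False, return_indices=True
    )
    window = np.clip(
        ndimage.gaussian_filter(
            ndimage.binary_dilation(lung, iterations=6).astype(float), 1.5
        ),
        0.0, 1.0,
    )
    amp = mean_j.astype(float).copy()
    lab_in = labels[lung]
    disp = np.zeros(shape + (3,))
    for _ in range(max(n_iters, 1)):
        j_target = np.ones(shape)
        j_target[lung] = amp[lab_in]
        j_target *= modulation
        j_ext = j_target[tuple(nearest)]
        g = integrate.cumulative_trapezoid(
            (j_ext - 1.0) * window, dx=spacing, axis=2, initial=0.0
        )
        disp[...] = 0.0
        disp[..., 2] = g
        jac = jacobian_determinant(disp, spacing, floor=None)
        realized = np.array(
            [jac[lung & (labels == i)].mean() if np.any(lung & (labels == i)) else 1.0
             for i in range(len(mean_j))]
        )
        amp = np.clip(amp * mean_j / realized, 0.2 * mean_j, 3.0 * mean_j)
    return disp


def generate_cohort(
    n_per_group: dict[str, int],
    group_mixtures: dict[str, dict[str, float]],
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: float = 1.0,
    patterns: dict[str, TissuePatternSpec] | None = None,
    covariate_shifts: dict[str, dict[str, float]] | None = None,
    mixture_concentration: float | None = 80.0,
) -> tuple[list[tuple[SubjectProfile, PairedLungScan]], pd.DataFrame]:
    """Generate a cohort whose groups differ through their pattern
    mixtures (and optionally through covariate shifts such as the gender
    proportion or exposure probability per group).

    ``mixture_concentration`` sets within-group Dirichlet variability
    around the group mixture (higher = tighter); ``None`` plants the
    exact group mixture in every subject.
    """
    if len(n_per_group) < 2:
        raise ValueError("need at least 2 groups")
    if set(n_per_group) != set(group_mixtures):
        raise ValueError("n_per_group and group_mixtures must list the same groups")
    if any(n < 1 for n in n_per_group.values()):
        raise ValueError("every group needs at least 1 subject")
    shifts = covariate_shifts or {}
    rng = np.random.default_rng(seed)

    records: list[tuple[SubjectProfile, PairedLungScan]] = []
    rows = []
    sid = 0
    for group in sorted(n_per_group):
        mix_names = list(group_mixtures[group])
        mix = np.asarray([group_mixtures[group][k] for k in mix_names], dtype=float)
        mix = mix / mix.sum()
        sh = shifts.get(group, {})
        gender_p = sh.get("gender_p", 0.5)       # P(male)
        exposure_p = sh.get("exposure_p", 0.5)
        for _ in range(n_per_group[group]):
            if mixture_concentration is None:
                m = mix
            else:
                m = rng.dirichlet(np.maximum(mix, 1e-6) * mixture_concentration)
                m = m / m.sum()
            gender = int(rng.random() < gender_p)
            height = rng.normal(172.0 if gender else 160.0, 7.0) + sh.get("height_shift", 0.0)
            weight = max(rng.normal(70.0 if gender else 60.0, 10.0) + sh.get("weight_shift", 0.0), 35.0)
            profile = SubjectProfile(
                subject_id=f"S{sid:03d}",
                group_id=group,
                pattern_mixture={k: float(v) for k, v in zip(mix_names, m / m.sum())},
                exposure=int(rng.random() < exposure_p),
                gender=gender,
                age=float(np.clip(rng.normal(50.0 + sh.get("age_shift", 0.0), 13.0), 20, 85)),
                height=float(height),
                weight=float(weight),
                fvc_pct=float(np.clip(rng.normal(92.0 + sh.get("fvc_shift", 0.0), 12.0), 40, 140)),
                fev1_pct=float(np.clip(rng.normal(95.0 + sh.get("fev1_shift", 0.0), 14.0), 40, 150)),
            )
            scan = generate_subject(
                profile, shape=shape, spacing=spacing,
                seed=int(rng.integers(0, 2**31 - 1)), patterns=patterns,
            )
            records.append((profile, scan))
            row = {
                "subject_id": profile.subject_id,
                "group_id": group,
                "exposure": profile.exposure,
                "gender": profile.gender,
                "age": profile.age,
                "height": profile.height,
                "weight": profile.weight,
                "fvc_pct": profile.fvc_pct,
                "fev1_pct": profile.fev1_pct,
            }
            row.update({f"mix_{k}": v for k, v in profile.pattern_mixture.items()})
            rows.append(row)
            sid += 1
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# airway tree
# ---------------------------------------------------------------------------

def generate_airway_tree(
    n_generations: int = 8,
    root_diameter: float = 16.0,
    reduction_ratio: float = 0.78,
    asymmetry: float = 0.0,
    seed: int = 0,
    length_to_diameter: float = 3.0,
) -> AirwayTree:
    """Rooted binary conducting-airway tree with circular lumens.

    Diameters shrink by ``reduction_ratio`` per generation (Weibel-like);
    ``asymmetry`` in [0, 1] splits sibling diameters by a factor
    (1 +/- asymmetry/2).  Lobar branches are labeled anatomically: the
    left main bronchus bifurcates into LUL and LLL, the right into RUL
    and the intermediate bronchus, which bifurcates into RML and RLL
    (present when n_generations >= 4); all other proximal branches are
    "central" and descendants inherit their lobe.
    """
    if n_generations < 3:
        raise ValueError("n_generations must be >= 3")
    if not (0.0 < reduction_ratio < 1.0):
        raise ValueError("reduction_ratio must lie in (0, 1) for a converging tree")
    if not (0.0 <= asymmetry <= 1.0):
        raise ValueError("asymmetry must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    branches: list[AirwayBranch] = []

    def add(parent, generation, diameter, lobe):
        bid = len(branches)
        length = length_to_diameter * diameter * float(
            np.exp(rng.normal(0.0, 0.05)) if asymmetry > 0 else 1.0
        )
        branches.append(
            AirwayBranch(
                id=bid,
                parent=parent,
                length=length,
                area=np.pi * diameter**2 / 4.0,
                perimeter=np.pi * diameter,
                generation=generation,
                lobe=lobe,
            )
        )
        return bid

    def child_lobe(parent_bid, parent_lobe, side):
        gen = branches[parent_bid].generation + 1
        if parent_lobe != "central":
            return parent_lobe
        if gen == 2:
            if parent_bid == 1:                      # left main
                return "LUL" if side == 0 else "LLL"
            return "RUL" if side == 0 else "central"  # right main -> RUL + intermedius
        if gen == 3:
            return "RML" if side == 0 else "RLL"      # intermedius children
        return "central"

    root = add(-1, 0, root_diameter, "central")
    frontier = [root]
    for gen in range(1, n_generations):
        nxt = []
        for pid in frontier:
            d_parent = 2.0 * np.sqrt(branches[pid].area / np.pi)
            for side in range(2):
                factor = 1.0 + (0.5 if side == 0 else -0.5) * asymmetry
                lobe = child_lobe(pid, branches[pid].lobe, side)
                cid = add(pid, gen, d_parent * reduction_ratio * factor, lobe)
                nxt.append(cid)
        frontier = nxt
    return AirwayTree(branches=branches, root=root)
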