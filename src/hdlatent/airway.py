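"""1D conducting-airway resistance and aerosol deposition surrogate.

Replaces a full 3D computational fluid-particle-dynamics stage with the
classic quasi-steady 1D description of the conducting tree: laminar
Poiseuille pressure drops per branch, and per-branch deposition
efficiencies for inertial impaction (Stokes-number fit), gravitational
sedimentation (Pich's inclined-tube formula for laminar flow) and
Brownian diffusion (Ingham's expression), combined as independent
mechanisms and propagated from the root to the leaves with flow-split
weights.

Units: lengths and diameters mm, areas mm^2, flows mL/s, pressures Pa,
particle diameter um, particle density g/cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AirwayBranch",
    "AirwayTree",
    "BreathWaveform",
    "DepositionResult",
    "hydraulic_diameter",
    "breathing_waveform",
    "pressure_drop",
    "deposition_1d",
    "settling_velocity",
    "cunningham_correction",
]

MU_AIR = 1.81e-5          # Pa s, dynamic viscosity of air
RHO_AIR = 1.2             # kg/m^3
K_BOLTZMANN = 1.380649e-23
MEAN_FREE_PATH_UM = 0.066  # air at body conditions
GRAVITY = 9.81            # m/s^2


@dataclass
class AirwayBranch:
    id: int
    parent: int              # -1 for root
    length: float            # mm
    area: float              # lumen cross-section, mm^2
    perimeter: float         # mm
    generation: int
    lobe: str = "central"    # LUL, LLL, RUL, RML, RLL or central
    flow: float = 0.0        # assigned by pressure_drop / deposition, mL/s

    def __post_init__(self) -> None:
        if self.length <= 0 or self.area <= 0 or self.perimeter <= 0:
            raise ValueError("length, area and perimeter must be positive")

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self.area, self.perimeter)


@dataclass
class AirwayTree:
    """Rooted tree of conducting-airway branches (child count <= 2)."""

    branches: list[AirwayBranch]
    root: int = 0
    _children: dict[int, list[int]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = {b.id for b in self.branches}
        if len(ids) != len(self.branches):
            raise ValueError("duplicate branch ids")
        roots = [b.id for b in self.branches if b.parent == -1]
        if roots != [self.root]:
            raise ValueError("tree must have exactly the declared root")
        children: dict[int, list[int]] = {b.id: [] for b in self.branches}
        for b in self.branches:
            if b.parent != -1:
                if b.parent not in children:
                    raise ValueError(f"branch {b.id} has unknown parent {b.parent}")
                children[b.parent].append(b.id)
        if any(len(c) > 2 for c in children.values()):
            raise ValueError("binary tree: child count must be <= 2")
        # reachability check (acyclic by construction of parent pointers)
        seen, stack = set(), [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValueError("cycle detected")
            seen.add(n)
            stack.extend(children[n])
        if seen != ids:
            raise ValueError("disconnected branches present")
        object.__setattr__(self, "_children", children)

    def children(self, branch_id: int) -> list[int]:
        return self._children[branch_id]

    def branch(self, branch_id: int) -> AirwayBranch:
        return next(b for b in self.branches if b.id == branch_id)

    def leaves(self) -> list[int]:
        return [i for i, c in self._children.items() if not c]

    def lobar_branches(self) -> dict[str, int]:
        """First branch per lobe along root-to-leaf order."""
        out: dict[str, int] = {}
        for b in sorted(self.branches, key=lambda b: (b.generation, b.id)):
            if b.lobe != "central" and b.lobe not in out:
                out[b.lobe] = b.id
        return out

    def sublobar_branches(self) -> dict[str, list[int]]:
        """Child and grandchild branches of each lobar branch."""
        out: dict[str, list[int]] = {}
        for lobe, bid in self.lobar_branches().items():
            kids = self.children(bid)
            grandkids = [g for k in kids for g in self.children(k)]
            out[lobe] = kids + grandkids
        return out

    def volume_ml(self) -> float:
        return sum(b.area * b.length for b in self.branches) / 1000.0

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": b.id, "parent": b.parent, "length_mm": b.length,
                    "area_mm2": b.area, "perimeter_mm": b.perimeter,
                    "generation": b.generation, "lobe": b.lobe,
                }
                for b in self.branches
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AirwayTree":
        branches = [
            AirwayBranch(
                id=int(r.id), parent=int(r.parent), length=float(r.length_mm),
                area=float(r.area_mm2), perimeter=float(r.perimeter_mm),
                generation=int(r.generation), lobe=str(r.lobe),
            )
            for r in df.itertuples()
        ]
        root = next(b.id for b in branches if b.parent == -1)
        return cls(branches=branches, root=root)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"root": self.root, "branches": self.to_frame().to_dict("records")}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AirwayTree":
        with open(path) as fh:
            obj = json.load(fh)
        return cls.from_frame(pd.DataFrame(obj["branches"]))


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """Dh = 4 A / P; equals the diameter for a circular lumen."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * area / perimeter


@dataclass
class BreathWaveform:
    """Half-sine inspiratory flow: Q(t) = Qp sin(pi t / T_insp)."""

    tidal_volume: float       # mL
    period: float             # s, full breath cycle
    time_to_peak: float       # s
    peak_flow: float          # mL/s

    @property
    def t_insp(self) -> float:
        return 2.0 * self.time_to_peak

    def flow(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        q = self.peak_flow * np.sin(np.pi * t / self.t_insp)
        return np.where((t >= 0) & (t <= self.t_insp), q, 0.0)


def breathing_waveform(weight: float, period: float = 4.8, time_to_peak: float = 1.2) -> BreathWaveform:
    """Subject-specific sinusoidal inspiration: tidal volume 7 mL/kg,
    peak at ``time_to_peak`` (inspiratory phase lasts twice that)."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    vt = 7.0 * weight
    t_insp = 2.0 * time_to_peak
    qp = np.pi * vt / (2.0 * t_insp)
    return BreathWaveform(tidal_volume=vt, period=period, time_to_peak=time_to_peak, peak_flow=qp)


# ---------------------------------------------------------------------------
# flows and pressure drops
# ---------------------------------------------------------------------------

def _branch_flows(tree: AirwayTree, inlet_flow: float, split_rule: str) -> dict[int, float]:
    flows = {tree.root: inlet_flow}
    order = sorted(tree.branches, key=lambda b: b.generation)
    for b in order:
        kids = tree.children(b.id)
        if not kids:
            continue
        q = flows[b.id]
        if split_rule == "symmetric":
            for k in kids:
                flows[k] = q / len(kids)
        elif split_rule == "area":
            total = sum(tree.branch(k).area for k in kids)
            for k in kids:
                flows[k] = q * tree.branch(k).area / total
        else:
            raise ValueError(f"unknown split_rule {split_rule!r}")
    return flows


def pressure_drop(
    tree: AirwayTree, inlet_flow: float, split_rule: str = "symmetric"
) -> pd.DataFrame:
    """Laminar Poiseuille pressure drop per branch and cumulative path
    pressure from the root.

    dP = 128 mu L Q / (pi Dh^4), with mm/mL/s inputs converted to SI.
    Returns a frame with per-branch flow (mL/s), dP (Pa) and the total
    pressure drop from the root inlet to the branch outlet (Pa).
    """
    flows = _branch_flows(tree, inlet_flow, split_rule)
    rows = {}
    for b in sorted(tree.branches, key=lambda b: b.generation):
        q_si = flows[b.id] * 1e-6               # mL/s -> m^3/s
        dh_m = b.hydraulic_diameter * 1e-3
        dp = 128.0 * MU_AIR * (b.length * 1e-3) * q_si / (np.pi * dh_m**4)
        upstream = rows[b.parent]["path_dp_pa"] if b.parent != -1 else 0.0
        rows[b.id] = {
            "id": b.id, "parent": b.parent, "generation": b.generation,
            "lobe": b.lobe, "flow_ml_s": flows[b.id], "dp_pa": dp,
            "path_dp_pa": upstream + dp,
            "resistance_pa_s_ml": dp / flows[b.id] if flows[b.id] > 0 else np.inf,
        }
    return pd.DataFrame([rows[b.id] for b in tree.branches]).set_index("id")


# ---------------------------------------------------------------------------
# deposition efficiencies
# ---------------------------------------------------------------------------

def cunningham_correction(diameter_um: float) -> float:
    kn = 2.0 * MEAN_FREE_PATH_UM / diameter_um
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def settling_velocity(diameter_um: float, density_g_cm3: float) -> float:
    """Stokes terminal settling velocity in m/s."""
    d = diameter_um * 1e-6
    rho = density_g_cm3 * 1000.0
    return rho * d**2 * GRAVITY * cunningham_correction(diameter_um) / (18.0 * MU_AIR)


def _diffusivity(diameter_um: float, temperature: float = 310.0) -> float:
    d = diameter_um * 1e-6
    return K_BOLTZMANN * temperature * cunningham_correction(diameter_um) / (3.0 * np.pi * MU_AIR * d)


def sedimentation_efficiency(
    velocity_m_s: float, length_m: float, radius_m: float,
    settling_m_s: float, angle_deg: float = 45.0,
) -> float:
    """Pich's gravitational deposition efficiency for fully developed
    laminar flow in a tube inclined at ``angle_deg`` from gravity-normal
    (0 deg = horizontal tube, where settling is most effective).

    eta = (2/pi) [2 k sqrt(1-k^(2/3)) - k^(1/3) sqrt(1-k^(2/3))
                  + arcsin(k^(1/3))],   k = (3/8) vs L cos(angle) / (u R)
    """
    if velocity_m_s <= 0:
        return 1.0
    kappa = 0.375 * settling_m_s * length_m * np.cos(np.deg2rad(angle_deg)) / (
        velocity_m_s * radius_m
    )
    kappa = min(kappa, 1.0)
    if kappa <= 0:
        return 0.0
    k13 = kappa ** (1.0 / 3.0)
    k23 = k13 * k13
    s = np.sqrt(max(1.0 - k23, 0.0))
    return float(np.clip((2.0 / np.pi) * (2.0 * kappa * s - k13 * s + np.arcsin(k13)), 0.0, 1.0))


def diffusion_efficiency(velocity_m_s: float, length_m: float, radius_m: float,
                         diffusivity_m2_s: float) -> float:
    """Ingham's laminar-flow diffusional deposition efficiency,
    Delta = D L / (4 u R^2)."""
    if velocity_m_s <= 0:
        return 1.0
    delta = diffusivity_m2_s * length_m / (4.0 * velocity_m_s * radius_m**2)
    eta = 1.0 - (
        0.819 * np.exp(-14.63 * delta)
        + 0.0976 * np.exp(-89.22 * delta)
        + 0.0325 * np.exp(-228.0 * delta)
        + 0.0509 * np.exp(-125.9 * delta ** (2.0 / 3.0))
    )
    return float(np.clip(eta, 0.0, 1.0))


def impaction_efficiency(stokes: float, coeffs: tuple[float, float] = (1.606, 0.0023)) -> float:
    """Linear Stokes-number fit for bronchial bifurcations,
    eta = a Stk + b, clipped to [0, 1]."""
    a, b = coeffs
    return float(np.clip(a * stokes + b, 0.0, 1.0)) if stokes > 0 else 0.0


@dataclass
class DepositionResult:
    per_branch: pd.DataFrame   # entering fraction, efficiencies, DF per branch
    total_df: float
    escape: float


def deposition_1d(
    tree: AirwayTree,
    waveform: BreathWaveform,
    particle_diameter_um: float = 0.5,
    particle_density_g_cm3: float = 1.0,
    branch_angle_deg: float = 45.0,
    split_rule: str = "symmetric",
    gravity_on: bool = True,
    diffusion_on: bool = True,
    impaction_on: bool = True,
) -> DepositionResult:
    """Per-branch deposition fractions for the conducting tree at the
    peak-inspiratory flow, propagated root -> leaves.

    Mass bookkeeping is exact: entering(parent) = DF(parent) +
    sum(entering(children)), and total DF + escape = 1.
    """
    if particle_diameter_um <= 0 or particle_density_g_cm3 <= 0:
        raise ValueError("particle parameters must be positive")
    flows = _branch_flows(tree, waveform.peak_flow, split_rule)
    vs = settling_velocity(particle_diameter_um, particle_density_g_cm3) if gravity_on else 0.0
    diff = _diffusivity(particle_diameter_um) if diffusion_on else 0.0

    entering = {tree.root: 1.0}
    rows = []
    total_df = 0.0
    escape = 0.0
    for b in sorted(tree.branches, key=lambda b: b.generation):
        q = flows[b.id]                            # mL/s
        u = q * 1e-6 / (b.area * 1e-6)             # m/s (mL/s->m^3/s over mm^2->m^2)
        dh_m = b.hydraulic_diameter * 1e-3
        length_m = b.length * 1e-3
        radius_m = dh_m / 2.0
        eta_s = sedimentation_efficiency(u, length_m, radius_m, vs, branch_angle_deg)
        eta_d = diffusion_efficiency(u, length_m, radius_m, diff)
        if impaction_on and b.parent != -1:
            d_m = particle_diameter_um * 1e-6
            stk = (
                particle_density_g_cm3 * 1000.0 * d_m**2 * u
                * cunningham_correction(particle_diameter_um)
                / (18.0 * MU_AIR * dh_m)
            )
            eta_i = impaction_efficiency(stk)
        else:
            eta_i = 0.0
        eta = 1.0 - (1.0 - eta_i) * (1.0 - eta_s) * (1.0 - eta_d)
        ent = entering[b.id]
        df = ent * eta
        total_df += df
        passed = ent - df
        kids = tree.children(b.id)
        if kids:
            q_kids = sum(flows[k] for k in kids)
            for k in kids:
                entering[k] = passed * flows[k] / q_kids
        else:
            escape += passed
        rows.append(
            {
                "id": b.id, "generation": b.generation, "lobe": b.lobe,
                "flow_ml_s": q, "velocity_m_s": u, "eta_impaction": eta_i,
                "eta_sedimentation": eta_s, "eta_diffusion": eta_d,
                "eta_total": eta, "entering": ent, "df": df,
            }
        )
    return DepositionResult(
        per_branch=pd.DataFrame(rows).set_index("id"),
        total_df=total_df,
        escape=escape,
    )
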