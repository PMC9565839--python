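"""Airway resistance and 1D deposition surrogate."""

import numpy as np
import pytest

from hdlatent.airway import (
    AirwayBranch,
    AirwayTree,
    breathing_waveform,
    deposition_1d,
    diffusion_efficiency,
    hydraulic_diameter,
    impaction_efficiency,
    pressure_drop,
    sedimentation_efficiency,
    settling_velocity,
)
from hdlatent.synthetic import generate_airway_tree


def _scaled_tree(tree: AirwayTree, factor: float) -> AirwayTree:
    branches = [
        AirwayBranch(
            id=b.id, parent=b.parent, length=b.length,
            area=b.area * factor**2, perimeter=b.perimeter * factor,
            generation=b.generation, lobe=b.lobe,
        )
        for b in tree.branches
    ]
    return AirwayTree(branches=branches, root=tree.root)


class TestHydraulicDiameter:
    def test_circle_recovers_diameter(self):
        d = 7.0
        assert hydraulic_diameter(np.pi * d**2 / 4, np.pi * d) == pytest.approx(d)

    def test_square_recovers_side(self):
        a = 3.0
        assert hydraulic_diameter(a * a, 4 * a) == pytest.approx(a)

    def test_arithmetic_example(self):
        assert hydraulic_diameter(3.0, 8.0) == 1.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            hydraulic_diameter(0.0, 4.0)


class TestBreathingWaveform:
    def test_tidal_volume_from_weight(self):
        assert breathing_waveform(60.0).tidal_volume == 420.0

    def test_peak_flow_value(self):
        wf = breathing_waveform(70.0)
        assert wf.peak_flow == pytest.approx(np.pi * 490.0 / (2 * 2.4), rel=1e-12)
        assert wf.peak_flow == pytest.approx(320.7, abs=0.1)

    def test_inspired_volume_integrates_to_tidal_volume(self):
        wf = breathing_waveform(65.0)
        t = np.linspace(0, wf.t_insp, 20001)
        vol = np.trapezoid(wf.flow(t), t)
        assert abs(vol - wf.tidal_volume) / wf.tidal_volume < 1e-3

    def test_peak_at_time_to_peak(self):
        wf = breathing_waveform(65.0, time_to_peak=1.2)
        assert wf.flow(1.2) == pytest.approx(wf.peak_flow)
        assert wf.flow(0.3) < wf.peak_flow

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            breathing_waveform(0.0)


class TestPressureDrop:
    def test_diameter_fourth_power_scaling(self):
        tree = generate_airway_tree(n_generations=4, seed=0)
        base = pressure_drop(tree, 300.0)
        narrowed = pressure_drop(_scaled_tree(tree, 0.5), 300.0)
        ratio = narrowed["dp_pa"] / base["dp_pa"]
        assert np.allclose(ratio, 16.0, rtol=1e-12)

    def test_symmetric_siblings_equal_drop(self):
        tree = generate_airway_tree(n_generations=4, asymmetry=0.0, seed=1)
        dp = pressure_drop(tree, 250.0)
        for b in tree.branches:
            kids = tree.children(b.id)
            if len(kids) == 2:
                assert dp.loc[kids[0], "dp_pa"] == pytest.approx(dp.loc[kids[1], "dp_pa"])

    def test_uniform_clone_path_ratio(self):
        # scaling all hydraulic diameters by 0.9 multiplies every path
        # pressure drop by 0.9^-4 (narrower airways, higher resistance)
        tree = generate_airway_tree(n_generations=5, asymmetry=0.2, seed=2)
        base = pressure_drop(tree, 300.0)
        clone = pressure_drop(_scaled_tree(tree, 0.9), 300.0)
        ratio = clone["path_dp_pa"] / base["path_dp_pa"]
        assert np.allclose(ratio, 0.9**-4, rtol=1e-12)

    def test_resistance_decreases_with_diameter(self):
        tree = generate_airway_tree(n_generations=3, seed=0)
        res = [
            pressure_drop(_scaled_tree(tree, f), 300.0)["resistance_pa_s_ml"].sum()
            for f in (0.8, 1.0, 1.25)
        ]
        assert res[0] > res[1] > res[2]

    def test_flow_conservation_at_bifurcations(self):
        tree = generate_airway_tree(n_generations=5, asymmetry=0.4, seed=3)
        dp = pressure_drop(tree, 300.0, split_rule="area")
        for b in tree.branches:
            kids = tree.children(b.id)
            if kids:
                assert dp.loc[kids, "flow_ml_s"].sum() == pytest.approx(
                    dp.loc[b.id, "flow_ml_s"])


class TestDeposition:
    def test_all_mechanisms_off_everything_escapes(self):
        tree = generate_airway_tree(n_generations=5, seed=0)
        wf = breathing_waveform(65.0)
        res = deposition_1d(tree, wf, gravity_on=False, diffusion_on=False,
                            impaction_on=False)
        assert res.total_df == pytest.approx(0.0, abs=1e-12)
        assert res.escape == pytest.approx(1.0)

    def test_mass_conservation_bookkeeping(self):
        tree = generate_airway_tree(n_generations=7, asymmetry=0.3, seed=1)
        res = deposition_1d(tree, breathing_waveform(70.0))
        assert res.total_df + res.escape == pytest.approx(1.0, abs=1e-9)
        pb = res.per_branch
        for b in tree.branches:
            kids = tree.children(b.id)
            if kids:
                assert pb.loc[b.id, "entering"] - pb.loc[b.id, "df"] == pytest.approx(
                    pb.loc[kids, "entering"].sum(), abs=1e-12)

    def test_efficiencies_bounded(self):
        tree = generate_airway_tree(n_generations=8, seed=2)
        res = deposition_1d(tree, breathing_waveform(60.0))
        for col in ("eta_impaction", "eta_sedimentation", "eta_diffusion", "eta_total"):
            assert res.per_branch[col].between(0.0, 1.0).all()

    def test_narrowing_does_not_decrease_total_df(self):
        # airway narrowing raises residence-time-driven deposition of
        # 0.5 um particles (the affected-cluster direction)
        tree = generate_airway_tree(n_generations=8, seed=3)
        wf = breathing_waveform(65.0)
        base = deposition_1d(tree, wf).total_df
        narrowed = deposition_1d(_scaled_tree(tree, 0.8), wf).total_df
        assert narrowed >= base

    def test_sedimentation_monotone_in_residence_time(self):
        etas = [
            sedimentation_efficiency(u, 0.02, 0.002, 1e-4, angle_deg=0.0)
            for u in (0.4, 0.2, 0.1, 0.05)
        ]
        assert etas == sorted(etas)

    def test_diffusion_monotone_in_residence_time(self):
        etas = [diffusion_efficiency(u, 0.02, 0.002, 1e-9) for u in (0.4, 0.1, 0.02)]
        assert etas == sorted(etas)

    def test_impaction_fit_clipped(self):
        assert impaction_efficiency(0.0) == 0.0
        assert impaction_efficiency(10.0) == 1.0

    def test_unphysical_particle_rejected(self):
        tree = generate_airway_tree(n_generations=4, seed=0)
        with pytest.raises(ValueError):
            deposition_1d(tree, breathing_waveform(60.0), particle_diameter_um=-1.0)

    def test_sedimentation_matches_particle_tracking_oracle(self):
        # independent Monte-Carlo oracle: flux-weighted entry into
        # laminar Poiseuille flow with gravitational settling, explicit
        # trajectory integration
        def mc(u_mean, length, radius, vs, n=200_000, seed=0, nstep=3000):
            rng = np.random.default_rng(seed)
            xs = []
            while sum(len(a) for a in xs) < n:
                x = rng.uniform(-radius, radius, 2 * n)
                y = rng.uniform(-radius, radius, 2 * n)
                r2 = x * x + y * y
                keep = r2 < radius**2
                acc = rng.random(keep.sum()) < 1 - r2[keep] / radius**2
                xs.append(np.stack([x[keep][acc], y[keep][acc]], axis=1))
            pos = np.concatenate(xs)[:n]
            x, y = pos[:, 0], pos[:, 1].copy()
            z = np.zeros(n)
            alive = np.ones(n, bool)
            deposited = np.zeros(n, bool)
            dt = 2.2 * radius / vs / nstep
            for _ in range(nstep):
                u = 2 * u_mean * (1 - (x * x + y * y) / radius**2)
                z[alive] += u[alive] * dt
                y[alive] -= vs * dt
                hit = alive & (x * x + y * y >= radius**2)
                deposited |= hit & (z <= length)
                alive &= ~hit & (z < length)
                if not alive.any():
                    break
            return deposited.mean()

        u, length, radius, vs = 0.05, 0.02, 0.001, 2e-4
        analytic = sedimentation_efficiency(u, length, radius, vs, angle_deg=0.0)
        oracle = mc(u, length, radius, vs)
        assert abs(analytic - oracle) / oracle < 0.02

    def test_settling_velocity_half_micron_magnitude(self):
        # ~1e-5 m/s for a unit-density 0.5 um sphere (slip-corrected)
        vs = settling_velocity(0.5, 1.0)
        assert 5e-6 < vs < 2e-5


class TestTreeValidation:
    def test_cycle_and_orphan_rejected(self):
        good = generate_airway_tree(n_generations=3, seed=0)
        branches = [AirwayBranch(b.id, b.parent, b.length, b.area, b.perimeter,
                                 b.generation, b.lobe) for b in good.branches]
        branches[0] = AirwayBranch(0, 6, branches[0].length, branches[0].area,
                                   branches[0].perimeter, 0, "central")
        with pytest.raises(ValueError):
            AirwayTree(branches=branches, root=0)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            AirwayBranch(0, -1, 0.0, 1.0, 1.0, 0)
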