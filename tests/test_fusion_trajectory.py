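"""Branch assembly, radius minimisation and barrier location."""

import numpy as np
import pytest

from pexofusion import (
    DimpleState,
    EnergyProfile,
    FusionGeometry,
    GapState,
    barrier_vs_H0,
    defect_branch,
    defect_elastic_energy,
    dimple_branch,
    dimple_elastic_energy,
    energy_profile,
    find_barrier,
    hydration_energy,
    hydrophobic_energy,
)


class TestDimpleBranch:
    def test_flat_start_costs_nothing(self, dopc, mono_geometry, bil_geometry):
        mono, inter = dopc
        for geom in (mono_geometry, bil_geometry):
            w1, r = dimple_branch(0.0, geom, mono, inter)
            assert w1 == 0.0
            assert r > 0.0

    def test_strictly_increasing_along_reaction_coordinate(self, dopc, mono_geometry):
        mono, inter = dopc
        H = np.linspace(0.0, 3.0, 40)
        w = [dimple_branch(h, mono_geometry, mono, inter)[0] for h in H]
        assert all(b > a for a, b in zip(w, w[1:]))

    def test_reported_radius_is_a_minimum(self, dopc, mono_geometry):
        mono, inter = dopc
        H = 1.5
        w1, r_min = dimple_branch(H, mono_geometry, mono, inter)

        def objective(R):
            return dimple_elastic_energy(DimpleState(R=R, H=H), mono) + (
                hydration_energy(
                    GapState(footprint_radius=R, gap=mono_geometry.gap(H)),
                    mono_geometry.H0, inter))

        assert objective(r_min) == pytest.approx(w1, rel=1e-10)
        for delta in (-0.05, 0.05):
            assert objective(r_min + delta) > w1

    def test_out_of_range_height_raises(self, dopc, mono_geometry, bil_geometry):
        mono, inter = dopc
        with pytest.raises(ValueError):
            dimple_branch(3.5, mono_geometry, mono, inter)
        with pytest.raises(ValueError):
            dimple_branch(2.0, bil_geometry, mono, inter)  # bilayer range is H0/2


class TestDefectBranch:
    def test_starts_above_dimple_branch(self, dopc, mono_geometry):
        # at H = 0 the defect still pays the bare hydrophobic cost
        mono, inter = dopc
        w1, r = dimple_branch(0.0, mono_geometry, mono, inter)
        w2 = defect_branch(0.0, r, mono_geometry, mono, inter)
        assert w2 > w1 == 0.0

    def test_endpoint_is_pure_rim_energy(self, dopc, mono_geometry):
        # at stalk contact the hydrophobic interaction vanishes
        mono, inter = dopc
        rho = 1.1
        w2 = defect_branch(3.0, rho, mono_geometry, mono, inter)
        assert w2 == pytest.approx(defect_elastic_energy(rho, 3.0, mono), rel=1e-12)

    def test_bilayer_decomposition_identity(self, dopc, bil_geometry):
        mono, inter = dopc
        H, rho = 1.0, 0.9
        expected = (
            2.0 * dimple_elastic_energy(DimpleState(R=rho, H=H), mono)
            + 2.0 * defect_elastic_energy(rho, H, mono)
            + hydrophobic_energy(
                GapState(footprint_radius=rho, gap=bil_geometry.gap(H)), inter)
        )
        assert defect_branch(H, rho, bil_geometry, mono, inter) == (
            pytest.approx(expected, rel=1e-12))


class TestEnergyProfile:
    def test_single_branch_crossing(self, dopc, mono_geometry):
        mono, inter = dopc
        prof = energy_profile(mono_geometry, mono, inter)
        sign_changes = np.sum(np.diff(np.sign(prof.W1 - prof.W2)[1:]) != 0)
        assert sign_changes == 1

    def test_deterministic_and_aligned(self, dopc, mono_geometry):
        mono, inter = dopc
        a = energy_profile(mono_geometry, mono, inter, n_points=120)
        b = energy_profile(mono_geometry, mono, inter, n_points=120)
        assert np.array_equal(a.W1, b.W1)
        assert np.array_equal(a.W2, b.W2)
        assert np.array_equal(a.R_min, b.R_min)
        assert a.H_grid.shape == a.W1.shape == a.W2.shape == a.R_min.shape
        assert np.all(np.diff(a.H_grid) > 0)
        assert np.all(a.R_min > 0)

    def test_too_coarse_grid_rejected(self, dopc, mono_geometry):
        mono, inter = dopc
        with pytest.raises(ValueError):
            energy_profile(mono_geometry, mono, inter, n_points=10)

    def test_dataframe_columns_carry_units(self, dopc, mono_geometry):
        mono, inter = dopc
        df = energy_profile(mono_geometry, mono, inter, n_points=60).to_dataframe()
        assert list(df.columns) == ["H_nm", "W1_kBT", "W2_kBT", "Rmin_nm"]


class TestFindBarrier:
    def test_barrier_is_dimple_energy_at_crossing(self, dopc, mono_geometry):
        mono, inter = dopc
        prof = energy_profile(mono_geometry, mono, inter)
        res = find_barrier(prof, mono, inter)
        assert 0.0 < res.H_star < mono_geometry.H0
        w1, _ = dimple_branch(res.H_star, mono_geometry, mono, inter)
        assert res.E == pytest.approx(w1, rel=1e-12)
        # just before the crossing the defect branch still lies above
        w1m, rm = dimple_branch(res.H_star - 0.01, mono_geometry, mono, inter)
        assert defect_branch(res.H_star - 0.01, rm, mono_geometry, mono, inter) > w1m

    def test_stalk_energy_matches_endpoint(self, dopc, mono_geometry):
        mono, inter = dopc
        res = find_barrier(energy_profile(mono_geometry, mono, inter), mono, inter)
        _, r_end = dimple_branch(3.0, mono_geometry, mono, inter)
        assert res.stalk_energy == pytest.approx(
            defect_elastic_energy(r_end, 3.0, mono), rel=1e-12)

    def test_monolayer_stalk_is_metastable(self, dopc, mono_geometry):
        # with DOPC parameters the stalk endpoint lies below the flat state
        mono, inter = dopc
        res = find_barrier(energy_profile(mono_geometry, mono, inter), mono, inter)
        assert res.stalk_energy < 0.0

    def test_grid_refinement_stability(self, dopc, mono_geometry):
        mono, inter = dopc
        e400 = find_barrier(
            energy_profile(mono_geometry, mono, inter, 400), mono, inter).E
        e800 = find_barrier(
            energy_profile(mono_geometry, mono, inter, 800), mono, inter).E
        assert abs(e400 - e800) < 0.1

    def test_no_crossing_is_reported(self, dopc, mono_geometry):
        mono, inter = dopc
        H = np.linspace(0.0, 3.0, 60)
        fake = EnergyProfile(
            geometry=mono_geometry,
            H_grid=H,
            W1=np.zeros_like(H),
            W2=np.ones_like(H),  # defect branch never comes down
            R_min=np.ones_like(H),
        )
        with pytest.raises(ValueError, match="no barrier crossing"):
            find_barrier(fake, mono, inter)


class TestBarrierSweep:
    def test_barrier_grows_with_separation(self, dopc):
        mono, inter = dopc
        df = barrier_vs_H0("monolayer_bilayer", mono, inter,
                           H0_values=[2.0, 3.0, 4.0], n_points=200)
        assert (df["error"] == "").all()
        assert df["E_kBT"].is_monotonic_increasing

    def test_monolayer_fusion_is_easier_than_bilayer(self, dopc):
        mono, inter = dopc
        H0s = [2.0, 3.0]
        e_mono = barrier_vs_H0("monolayer_bilayer", mono, inter, H0s, 200)["E_kBT"]
        e_bil = barrier_vs_H0("bilayer_bilayer", mono, inter, H0s, 200)["E_kBT"]
        assert (e_mono.values < e_bil.values).all()
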