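import numpy as np
import pytest

from chargereg import (
    LevelSpec,
    SaltBath,
    SolverOptions,
    SurfaceModel,
    henderson_hasselbalch,
    relative_increase,
    solve_point,
    solve_point_bruteforce,
    sweep,
)

LEVEL_OFF = LevelSpec(False, False, False, False)


class TestLevelSpec:
    def test_named_presets(self):
        assert LevelSpec.preset("a") == LevelSpec(True, True, False, False)
        assert LevelSpec.preset("b") == LevelSpec(True, True, True, False)
        assert LevelSpec.preset("c") == LevelSpec(True, True, False, True)
        assert LevelSpec.preset("d") == LevelSpec(True, True, True, True)
        assert LevelSpec.preset("D").name == "d"

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            LevelSpec.preset("x")


class TestSolvePoint:
    def test_all_corrections_off_recovers_ideal_titration(
        self, silica_model, molar_1_1, molar_2_1
    ):
        for bath in (molar_1_1, molar_2_1):
            for pH in (4.0, 7.7, 9.0):
                pt = solve_point(pH, silica_model, bath, LEVEL_OFF)
                assert pt.converged
                assert pt.alpha == pytest.approx(
                    henderson_hasselbalch(pH, silica_model), abs=1e-10
                )
                assert pt.x_site == 0.0

    def test_converged_point_is_self_consistent(self, silica_model, molar_1_1):
        pt = solve_point(9.0, silica_model, molar_1_1, LevelSpec.preset("d"))
        assert pt.converged
        assert abs(pt.alpha + pt.sigma / silica_model.site_density) < 1e-10
        assert 0 < pt.alpha < 1
        assert pt.sigma < 0 and pt.sigma_SI < 0

    def test_mean_field_diagnostic_decomposition(self, silica_model, molar_1_1):
        pt = solve_point(8.0, silica_model, molar_1_1, LevelSpec.preset("d"))
        bd = pt.breakdown
        assert pt.x_mf == pytest.approx(pt.x_ion - bd.x_ii - bd.x_ex, rel=1e-12)
        assert pt.x_site == pytest.approx(pt.x_mf + bd.x_cap + bd.x_ss, rel=1e-12)

    def test_sign_contracts_of_each_correction(self, silica_model, molar_2_1):
        pH = 8.5
        base = solve_point(pH, silica_model, molar_2_1, LevelSpec.preset("a"))
        with_ss = solve_point(pH, silica_model, molar_2_1, LevelSpec.preset("b"))
        with_ii = solve_point(pH, silica_model, molar_2_1, LevelSpec.preset("c"))
        no_dl = solve_point(pH, silica_model, molar_2_1, LEVEL_OFF)
        assert with_ss.alpha > base.alpha  # site ordering promotes ionization
        assert with_ii.alpha > base.alpha  # counterion correlations promote it
        assert base.alpha < no_dl.alpha  # double-layer feedback suppresses it

    def test_potential_breakdown_signs(self, silica_model, molar_2_1):
        bd = solve_point(8.5, silica_model, molar_2_1, LevelSpec.preset("d")).breakdown
        assert bd.x_cap < 0 and bd.x_ex < 0 and bd.x_ss > 0 and bd.x_ii < 0
        assert bd.z_s > 0 and bd.Xi > 0

    def test_agrees_with_bisection_oracle_on_random_configurations(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            model = SurfaceModel(
                bjerrum_length=float(rng.uniform(0.5, 1.0)),
                site_density=float(rng.uniform(1.0, 6.0)),
                pKa=float(rng.uniform(4.0, 9.0)),
                zeta=float(rng.uniform(0.0, 1.0)),
                xi2=float(rng.uniform(1.0, 2.0)),
            )
            bath = SaltBath.z_one(int(rng.integers(1, 3)), float(rng.uniform(0.01, 1.5)))
            level = LevelSpec(True, *(bool(rng.integers(0, 2)) for _ in range(3)))
            pH = float(rng.uniform(2.0, 12.0))
            fp = solve_point(pH, model, bath, level)
            bf = solve_point_bruteforce(pH, model, bath, level)
            assert fp.converged and bf.converged
            assert abs(fp.sigma - bf.sigma) < 1e-8

    def test_bruteforce_on_reference_system_across_pH(self, silica_model, molar_1_1):
        for pH in range(4, 10):
            fp = solve_point(float(pH), silica_model, molar_1_1, LevelSpec.preset("d"))
            bf = solve_point_bruteforce(
                float(pH), silica_model, molar_1_1, LevelSpec.preset("d")
            )
            assert abs(fp.sigma - bf.sigma) < 1e-8

    def test_degenerate_bath_propagates_no_solution(self, silica_model):
        empty = SaltBath(species=())
        with pytest.raises(Exception, match="zero total concentration"):
            solve_point(7.0, silica_model, empty, LevelSpec.preset("a"))

    def test_solver_options_validation(self):
        with pytest.raises(ValueError):
            SolverOptions(damping=0.0)
        with pytest.raises(ValueError):
            SolverOptions(tol=-1.0)


class TestSweep:
    def test_empty_grid(self, silica_model, molar_1_1):
        curve = sweep(silica_model, molar_1_1, LevelSpec.preset("a"), [])
        assert len(curve) == 0

    def test_unsorted_grid_rejected(self, silica_model, molar_1_1):
        with pytest.raises(ValueError, match="ascending"):
            sweep(silica_model, molar_1_1, LevelSpec.preset("a"), [7.0, 5.0])

    def test_ionization_monotone_in_pH(self, silica_model, molar_1_1):
        grid = np.arange(4.0, 9.01, 0.25)
        curve = sweep(silica_model, molar_1_1, LevelSpec.preset("d"), grid)
        assert curve.all_converged
        assert np.all(np.diff(curve.alpha) > 0)

    def test_concentration_ordering_of_1_1_curves(self, silica_model):
        grid = np.arange(4.0, 9.01, 0.5)
        curves = [
            sweep(silica_model, SaltBath.z_one(1, c), LevelSpec.preset("d"), grid)
            for c in (0.01, 0.1, 1.0)
        ]
        # more salt screens the surface better: higher ionization everywhere
        assert np.all(curves[1].alpha > curves[0].alpha)
        assert np.all(curves[2].alpha > curves[1].alpha)

    def test_warm_start_matches_cold_solutions(self, silica_model, molar_2_1):
        grid = [5.0, 7.0, 9.0]
        curve = sweep(silica_model, molar_2_1, LevelSpec.preset("d"), grid)
        for pH, pt in zip(grid, curve):
            cold = solve_point(pH, silica_model, molar_2_1, LevelSpec.preset("d"))
            assert pt.alpha == pytest.approx(cold.alpha, abs=1e-10)

    def test_dataframe_schema(self, silica_model, molar_1_1):
        curve = sweep(silica_model, molar_1_1, LevelSpec.preset("b"), [6.0, 7.0])
        df = curve.to_dataframe()
        assert list(df.columns) == [
            "pH", "alpha", "sigma_nm2", "sigma_mC_m2", "x_ion", "x_site", "x_mf",
            "x_cap", "x_ex", "x_ss", "x_ii", "z_s", "Xi", "iterations", "converged",
        ]
        assert (df["x_ii"] == 0).all()  # disabled term contributes exactly 0


class TestRelativeIncrease:
    def test_identical_curves_give_zero(self, silica_model, molar_1_1):
        grid = [6.0, 7.0, 8.0]
        c1 = sweep(silica_model, molar_1_1, LevelSpec.preset("a"), grid)
        c2 = sweep(silica_model, molar_1_1, LevelSpec.preset("a"), grid)
        assert np.allclose(relative_increase(c1, c2), 0.0, atol=1e-10)

    def test_grid_mismatch_rejected(self, silica_model, molar_1_1):
        c1 = sweep(silica_model, molar_1_1, LevelSpec.preset("a"), [6.0, 7.0])
        c2 = sweep(silica_model, molar_1_1, LevelSpec.preset("a"), [6.0, 8.0])
        with pytest.raises(ValueError, match="grid"):
            relative_increase(c1, c2)


class TestNonlinearScreening:
    def test_debye_equivalent_salts_differ_at_mean_field(self, silica_model):
        # 200 mM 1:1 and 67 mM 2:1 share a Debye length, yet the nonlinear
        # boundary condition ionizes the divalent case more at high pH
        pt_11 = solve_point(9.0, silica_model, SaltBath.z_one(1, 0.2), LevelSpec.preset("a"))
        pt_21 = solve_point(9.0, silica_model, SaltBath.z_one(2, 0.2 / 3), LevelSpec.preset("a"))
        assert pt_21.alpha - pt_11.alpha > 0
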