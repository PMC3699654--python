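"""Forward buoyant-mass model and the closed-form inversions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smrdry import (
    CellSpec,
    DegenerateInputError,
    FluidSpec,
    MatchedDensityError,
    MeasurementPair,
    forward_buoyant_mass,
    percent_dry,
    solve_dry,
    solve_total,
    solve_water,
)
from smrdry.fluids import RHO_H2O

cell_masses = st.floats(min_value=1.0, max_value=1e6)
cell_densities = st.floats(min_value=1.05, max_value=2.0)
water_volumes = st.floats(min_value=0.0, max_value=1e6)
fluid_densities = st.floats(min_value=0.9, max_value=1.25)


def _permeable(label, rho):
    # Pure-fluid idealization: water equilibrates to the fluid's own density.
    return FluidSpec(label, rho, True, rho)


class TestForwardModel:
    @pytest.mark.parametrize(
        "rho_f,expected",
        [(1.005, 57.275), (1.101, 43.355)],
    )
    def test_dry_only_cell(self, rho_f, expected):
        """A water-free 203 fg, 1.40 g/cm^3 cell weighs m*(1 - rho_f/rho_dry)."""
        cell = CellSpec(dry_mass=203.0, dry_density=1.40, water_volume=0.0)
        mb = forward_buoyant_mass(cell, _permeable("f", rho_f))
        assert mb == pytest.approx(expected, abs=1e-9)

    def test_neutral_buoyancy_is_zero(self):
        cell = CellSpec(dry_mass=100.0, dry_density=1.1, water_volume=0.0)
        assert forward_buoyant_mass(cell, _permeable("f", 1.1)) == pytest.approx(0.0)

    def test_impermeable_fluid_forces_native_water(self, fluids):
        """In an impermeable fluid the water term uses the native density."""
        cell = CellSpec(203.0, 1.40, water_volume=517.0, water_density=RHO_H2O)
        opti = fluids["optiprep_pbs"]
        mb = forward_buoyant_mass(cell, opti, residual_h2o_fraction=0.0)
        expected = 203.0 * (1 - opti.density / 1.40) + 517.0 * (RHO_H2O - opti.density)
        assert mb == pytest.approx(expected, rel=1e-12)

    def test_residual_fraction_interpolates_linearly(self, fluids):
        cell = CellSpec(203.0, 1.40, water_volume=500.0)
        f2 = fluids["pbs_d2o"]
        mb0 = forward_buoyant_mass(cell, f2, 0.0)
        mb1 = forward_buoyant_mass(cell, f2, 1.0)
        mbh = forward_buoyant_mass(cell, f2, 0.5)
        assert mbh == pytest.approx(0.5 * (mb0 + mb1), rel=1e-12)

    @given(m=cell_masses, rho=cell_densities, vw=water_volumes)
    def test_monotone_decreasing_in_fluid_density(self, m, rho, vw):
        """d(mb)/d(rho_f) = -(V_dry + V_w): buoyant mass falls with fluid density."""
        cell = CellSpec(m, rho, vw, water_density=1.0)
        f_lo = FluidSpec("lo", 1.00, True, 1.0)
        f_hi = FluidSpec("hi", 1.10, True, 1.0)
        mb_lo = forward_buoyant_mass(cell, f_lo, 1.0)
        mb_hi = forward_buoyant_mass(cell, f_hi, 1.0)
        slope = (mb_hi - mb_lo) / 0.10
        assert slope == pytest.approx(-(cell.dry_volume + vw), rel=1e-6, abs=1e-9)

    def test_rejects_bad_residual_fraction(self, fluids):
        cell = CellSpec(100.0, 1.4)
        with pytest.raises(ValueError):
            forward_buoyant_mass(cell, fluids["pbs_h2o"], 1.5)


class TestSolveDry:
    def test_worked_example(self, fluids):
        pair = MeasurementPair("c", 57.275, fluids["pbs_h2o"], 43.355, fluids["pbs_d2o"])
        res = solve_dry(pair)
        assert res.dry_mass == pytest.approx(203.0, rel=1e-9)
        assert res.dry_volume == pytest.approx(145.0, rel=1e-9)
        assert res.dry_density == pytest.approx(1.400, rel=1e-9)
        assert res.valid

    @given(m=cell_masses, rho=cell_densities, vw=water_volumes,
           r1=st.floats(0.99, 1.01), r2=st.floats(1.08, 1.11))
    def test_round_trip_recovers_cell(self, m, rho, vw, r1, r2):
        """Forward then inverse reproduces (dry mass, volume, density) to 1e-9."""
        f1, f2 = _permeable("a", r1), _permeable("b", r2)
        cell = CellSpec(m, rho, vw, water_density=RHO_H2O)
        pair = MeasurementPair(
            "c",
            forward_buoyant_mass(cell, f1, 0.0),
            f1,
            forward_buoyant_mass(cell, f2, 0.0),
            f2,
        )
        res = solve_dry(pair)
        assert res.dry_mass == pytest.approx(m, rel=1e-9, abs=1e-9)
        assert res.dry_volume == pytest.approx(cell.dry_volume, rel=1e-9, abs=1e-9)
        assert res.dry_density == pytest.approx(rho, rel=1e-9)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_density_scale_invariance(self, c, fluids):
        """Scaling both buoyant masses by c > 0 leaves dry density unchanged."""
        f1, f2 = fluids["pbs_h2o"], fluids["pbs_d2o"]
        base = solve_dry(MeasurementPair("c", 57.275, f1, 43.355, f2))
        scaled = solve_dry(MeasurementPair("c", c * 57.275, f1, c * 43.355, f2))
        assert scaled.dry_density == pytest.approx(base.dry_density, rel=1e-9)

    def test_water_volume_invariance_under_full_exchange(self):
        """With water at each fluid's own density, solve_dry ignores V_w."""
        f1, f2 = _permeable("a", 1.005), _permeable("b", 1.101)
        base = None
        for vw in np.linspace(0.0, 10 * 145.0, 7):
            cell = CellSpec(203.0, 1.40, float(vw))
            pair = MeasurementPair(
                "c",
                forward_buoyant_mass(cell, f1, 0.0),
                f1,
                forward_buoyant_mass(cell, f2, 0.0),
                f2,
            )
            res = solve_dry(pair)
            if base is None:
                base = res
            assert res.dry_mass == pytest.approx(base.dry_mass, rel=1e-9)
            assert res.dry_density == pytest.approx(base.dry_density, rel=1e-9)

    def test_equal_buoyant_masses_invalid(self, fluids):
        res = solve_dry(
            MeasurementPair("c", 10.0, fluids["pbs_h2o"], 10.0, fluids["pbs_d2o"])
        )
        assert res.dry_volume == 0.0
        assert not res.valid
        assert np.isnan(res.dry_density)

    def test_equal_fluid_densities_degenerate(self):
        f = _permeable("a", 1.05)
        g = _permeable("b", 1.05)
        with pytest.raises(DegenerateInputError):
            solve_dry(MeasurementPair("c", 1.0, f, 2.0, g))

    def test_impermeable_fluid_rejected(self, fluids):
        with pytest.raises(DegenerateInputError):
            solve_dry(
                MeasurementPair("c", 1.0, fluids["optiprep_pbs"], 2.0, fluids["pbs_d2o"])
            )

    def test_validity_consistency(self, fluids):
        """When valid, density equals mass/volume to machine precision."""
        res = solve_dry(
            MeasurementPair("c", 57.0, fluids["pbs_h2o"], 43.0, fluids["pbs_d2o"])
        )
        assert res.valid
        assert res.dry_density == pytest.approx(res.dry_mass / res.dry_volume, rel=1e-12)


class TestSolveWater:
    def test_worked_example(self, fluids):
        """mb1 - mb2 = -53.251 fg in a 1.101 fluid with rho_w = 0.998 -> 517 fL."""
        opti = fluids["optiprep_pbs"]
        d2o = FluidSpec("pbs_d2o", 1.101, True, 1.09335)
        res = solve_water(
            MeasurementPair("c", -40.0, opti, 13.251, d2o), water_density=0.998
        )
        assert res.water_volume == pytest.approx(517.0, rel=1e-9)
        assert res.water_mass == pytest.approx(515.966, abs=0.01)

    def test_equal_masses_zero_water(self, fluids):
        d2o = FluidSpec("pbs_d2o", 1.101, True, 1.09335)
        res = solve_water(MeasurementPair("c", 5.0, fluids["optiprep_pbs"], 5.0, d2o))
        assert res.water_mass == 0.0
        assert res.water_volume == 0.0

    def test_density_mismatch_rejected(self, fluids):
        opti = FluidSpec("opti", 1.111, False, RHO_H2O)
        d2o = FluidSpec("pbs_d2o", 1.101, True, 1.09335)
        with pytest.raises(MatchedDensityError):
            solve_water(MeasurementPair("c", 1.0, opti, 2.0, d2o))

    def test_wrong_permeability_rejected(self, fluids):
        with pytest.raises(DegenerateInputError):
            solve_water(
                MeasurementPair("c", 1.0, fluids["pbs_h2o"], 2.0, fluids["pbs_d2o"])
            )

    def test_fluid_at_water_density_degenerate(self):
        opti = FluidSpec("opti", 0.9975, False, RHO_H2O)
        h2o_like = FluidSpec("f2", 0.9975, True, 0.9975)
        with pytest.raises(DegenerateInputError):
            solve_water(MeasurementPair("c", 1.0, opti, 2.0, h2o_like))

    def test_forward_round_trip(self, fluids):
        """Forward model with V_w = 517 fL inverts back to 517 fL."""
        cell = CellSpec(203.0, 1.40, water_volume=517.0, water_density=RHO_H2O)
        opti = fluids["optiprep_pbs"]
        d2o = FluidSpec("pbs_d2o", 1.101, True, 1.101)
        mb1 = forward_buoyant_mass(cell, opti)
        mb2 = forward_buoyant_mass(cell, d2o, 0.0)
        res = solve_water(MeasurementPair("c", mb1, opti, mb2, d2o))
        assert res.water_volume == pytest.approx(517.0, rel=1e-9)


class TestSolveTotal:
    def test_round_trip(self):
        """A 727 fg, 626.72 fL particle is recovered from two impermeable fluids."""
        mass, vol = 727.0, 626.72
        rho = mass / vol
        f1 = FluidSpec("imp1", 1.005, False, RHO_H2O)
        f2 = FluidSpec("imp2", 1.101, False, RHO_H2O)
        mb1 = mass - vol * f1.density
        mb2 = mass - vol * f2.density
        res = solve_total(MeasurementPair("c", mb1, f1, mb2, f2))
        assert res.total_mass == pytest.approx(727.0, rel=1e-9)
        assert res.total_volume == pytest.approx(626.72, rel=1e-9)
        assert res.total_density == pytest.approx(rho, rel=1e-9)
        assert res.total_density == pytest.approx(1.160, abs=5e-4)

    def test_equal_masses_invalid(self):
        f1 = FluidSpec("imp1", 1.005, False, RHO_H2O)
        f2 = FluidSpec("imp2", 1.101, False, RHO_H2O)
        res = solve_total(MeasurementPair("c", 3.0, f1, 3.0, f2))
        assert res.total_volume == 0.0
        assert not res.valid

    @given(c=st.floats(min_value=1e-2, max_value=1e2))
    def test_scaling_masses_scales_extensives_only(self, c):
        f1 = FluidSpec("imp1", 1.005, False, RHO_H2O)
        f2 = FluidSpec("imp2", 1.101, False, RHO_H2O)
        base = solve_total(MeasurementPair("c", 97.2, f1, 37.0, f2))
        scaled = solve_total(MeasurementPair("c", c * 97.2, f1, c * 37.0, f2))
        assert scaled.total_mass == pytest.approx(c * base.total_mass, rel=1e-9)
        assert scaled.total_volume == pytest.approx(c * base.total_volume, rel=1e-9)
        assert scaled.total_density == pytest.approx(base.total_density, rel=1e-9)

    def test_permeable_fluid_rejected(self, fluids):
        f2 = FluidSpec("imp2", 1.101, False, RHO_H2O)
        with pytest.raises(DegenerateInputError):
            solve_total(MeasurementPair("c", 1.0, fluids["pbs_h2o"], 2.0, f2))


class TestPercentDry:
    def test_ecoli_medians(self):
        """Median dry 203 fg of total 727 fg is ~28% dry by mass."""
        by_mass, _ = percent_dry(203.0, 727.0, 145.0, 580.0)
        assert by_mass == pytest.approx(27.92, abs=0.01)
        assert round(by_mass) == 28

    def test_volume_fraction(self):
        _, by_vol = percent_dry(203.0, 727.0, 145.0, 580.0)
        assert by_vol == pytest.approx(20.0, abs=1e-9)

    def test_all_dry_is_100(self):
        by_mass, by_vol = percent_dry(100.0, 100.0, 70.0, 0.0)
        assert by_mass == 100.0
        assert by_vol == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateInputError):
            percent_dry(1.0, 0.0, 1.0, 1.0)


class TestConservation:
    @given(m=cell_masses, rho=cell_densities, vw=water_volumes)
    def test_decomposition_matches_whole_cell(self, m, rho, vw):
        """Dry + water terms equal the whole cell's m - V*rho_f."""
        cell = CellSpec(m, rho, vw, water_density=RHO_H2O)
        fluid = FluidSpec("f", 1.05, True, RHO_H2O)
        mb = forward_buoyant_mass(cell, fluid, residual_h2o_fraction=1.0)
        whole = cell.total_mass - cell.total_volume * fluid.density
        assert mb == pytest.approx(whole, rel=1e-9, abs=1e-6)

    def test_total_mass_is_dry_plus_water(self):
        cell = CellSpec(203.0, 1.40, 517.0, water_density=RHO_H2O)
        assert cell.total_mass == pytest.approx(203.0 + 517.0 * RHO_H2O, rel=1e-12)
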