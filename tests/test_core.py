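"""Constitutive laws: Poiseuille, tube law, Starling resistor, filtration,
aqueous drainage, transmural-pressure bookkeeping."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from eyebrain0d.core import (AqueousParameters, FluidProperties,
                             InvalidParameterError, PressureState,
                             SegmentedVessel, StarlingElement,
                             VesselGeometry, VesselWall,
                             cra_crv_segment_resistance, filtration_flux,
                             ohm_flux, poiseuille_resistance,
                             starling_resistance, trabecular_outflow,
                             transmural_pressures, tube_law_constants,
                             uveoscleral_outflow)
from eyebrain0d.params import REFERENCE
from eyebrain0d.units import (viscosity_mmhg_min_to_mmhg_s,
                              viscosity_mmhg_s_to_mmhg_min)

CRA_FLUID = FluidProperties.from_mmhg_s(2.25e-5)
CRA_AREA = math.pi * (175e-4) ** 2 / 4.0
VENULE_WALL = VesselWall(E=495.0, h=7.73e-4, nu=0.49)
VENULE_FLUID = FluidProperties.from_mmhg_s(2.12e-5)


class TestPoiseuille:
    def test_central_retinal_artery_segment(self):
        # independent hand evaluation of 8*pi*mu*L/A^2, mu converted to
        # mmHg*min: 0.44 cm of a 175 um vessel gives ~71.7 mmHg*min/ml
        geom = VesselGeometry(A=CRA_AREA, L=0.44)
        assert poiseuille_resistance(CRA_FLUID, geom) == pytest.approx(
            71.67898491576942, rel=1e-12)

    def test_linear_in_length(self):
        r1 = poiseuille_resistance(CRA_FLUID, VesselGeometry(A=CRA_AREA, L=0.2))
        r2 = poiseuille_resistance(CRA_FLUID, VesselGeometry(A=CRA_AREA, L=0.4))
        assert r2 == pytest.approx(2.0 * r1, rel=1e-14)

    def test_inverse_square_in_area(self):
        r1 = poiseuille_resistance(CRA_FLUID, VesselGeometry(A=1e-4, L=0.3))
        r2 = poiseuille_resistance(CRA_FLUID, VesselGeometry(A=4e-4, L=0.3))
        assert r1 == pytest.approx(16.0 * r2, rel=1e-12)

    @pytest.mark.parametrize("A,L", [(-1e-4, 0.3), (0.0, 0.3), (1e-4, -0.1)])
    def test_invalid_geometry_rejected(self, A, L):
        with pytest.raises(InvalidParameterError):
            VesselGeometry(A=A, L=L)

    def test_invalid_viscosity_rejected(self):
        with pytest.raises(InvalidParameterError):
            FluidProperties(mu=-1.0)


class TestTubeLaw:
    def test_retinal_venule_constants(self):
        # direct arithmetic oracle on the printed retinal venule geometry
        k_p, k_L = tube_law_constants(VENULE_WALL, 1.55e-4)
        assert k_L == pytest.approx(990.8412617661246, rel=1e-12)
        assert k_p == pytest.approx(0.07234911980992795, rel=1e-12)

    def test_wall_thickness_power_laws(self):
        wall2 = VesselWall(E=495.0, h=2 * 7.73e-4, nu=0.49)
        kp1, kL1 = tube_law_constants(VENULE_WALL, 1.55e-4)
        kp2, kL2 = tube_law_constants(wall2, 1.55e-4)
        assert kp2 == pytest.approx(8.0 * kp1, rel=1e-12)
        assert kL2 == pytest.approx(kL1 / 4.0, rel=1e-12)

    def test_poisson_ratio_scaling(self):
        kp0, _ = tube_law_constants(VesselWall(E=495.0, h=7.73e-4, nu=0.0),
                                    1.55e-4)
        kp49, _ = tube_law_constants(VesselWall(E=495.0, h=7.73e-4, nu=0.49),
                                     1.55e-4)
        assert kp49 == pytest.approx(kp0 / (1 - 0.49 ** 2), rel=1e-12)

    def test_incompressible_wall_rejected(self):
        with pytest.raises(InvalidParameterError):
            VesselWall(E=495.0, h=7.73e-4, nu=0.5)


class TestStarlingResistor:
    GEOM = VesselGeometry(A=1.55e-4, L=0.8)

    def test_branches_join_at_zero_transmural_pressure(self):
        r0 = poiseuille_resistance(VENULE_FLUID, self.GEOM)
        r_plus = starling_resistance(1e-300, VENULE_FLUID, self.GEOM,
                                     VENULE_WALL)
        r_minus = starling_resistance(-1e-300, VENULE_FLUID, self.GEOM,
                                      VENULE_WALL)
        assert r_plus == pytest.approx(r0, rel=1e-12)
        assert r_minus == pytest.approx(r0, rel=1e-12)
        assert starling_resistance(0.0, VENULE_FLUID, self.GEOM,
                                   VENULE_WALL) == pytest.approx(r0, rel=1e-12)

    def test_strictly_decreasing_for_all_shipped_elements(self, params):
        # distension widens the lumen, collapse chokes it: resistance must
        # fall monotonically with transmural pressure for every deformable
        # element actually shipped in the default model
        dps = [(-50 + 0.5 * i) for i in range(201)]
        elements = list(params.venules.values()) + [
            params.crv.segment(n) for n in (1, 2, 3, 4)]
        for elem in elements:
            rs = [elem.resistance(dp) for dp in dps]
            assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_collapse_branch_diverges(self):
        r1 = starling_resistance(-50.0, VENULE_FLUID, self.GEOM, VENULE_WALL)
        r2 = starling_resistance(-500.0, VENULE_FLUID, self.GEOM, VENULE_WALL)
        assert r2 > r1 > poiseuille_resistance(VENULE_FLUID, self.GEOM)


class TestFiltration:
    def test_blood_brain_barrier_baseline(self):
        # printed brain operating point reproduces the printed filtration
        q = filtration_flux(K=0.0665, sigma=1.0, dP=34.1543 - 11.2125,
                            dpi=21.0)
        assert q == pytest.approx(0.1291, abs=5e-5)

    def test_aqueous_ultrafiltration_baseline(self):
        # net absorption at baseline: the oncotic pull exceeds the
        # hydraulic push across the ciliary capillary wall
        q = filtration_flux(K=0.3e-3, sigma=1.0, dP=27.7616 - 14.9662,
                            dpi=25.0)
        assert q == pytest.approx(-3.66138e-3, rel=1e-6)
        assert round(q, 4) == -0.0037

    def test_zero_conductance(self):
        assert filtration_flux(0.0, 0.5, 12.3, -4.5) == 0.0

    @given(st.floats(-100, 100), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None, database=None,
              derandomize=True)
    def test_linear_in_pressure_difference(self, dP, dpi):
        q1 = filtration_flux(0.1, 0.8, dP, dpi)
        q2 = filtration_flux(0.1, 0.8, dP + 7.0, dpi)
        assert q2 - q1 == pytest.approx(0.7, abs=1e-9)


class TestOhm:
    def test_ventricular_outflow_baseline(self):
        q = ohm_flux(11.2125, 11.0119, 0.6678)
        assert q == pytest.approx(0.3004, abs=5e-5)

    def test_no_flow_without_gradient(self):
        assert ohm_flux(7.0, 7.0, 3.3) == 0.0

    @given(st.floats(-50, 150), st.floats(-50, 150),
           st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None, database=None,
              derandomize=True)
    def test_antisymmetric(self, a, b, r):
        assert ohm_flux(a, b, r) == pytest.approx(-ohm_flux(b, a, r),
                                                  abs=1e-9)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(InvalidParameterError):
            ohm_flux(10.0, 0.0, 0.0)


@pytest.fixture
def aqueous():
    return AqueousParameters(L_in=0.3e-3, sigma_p=1.0, delta_pi_p=25.0,
                             k1=0.4e-3, k2=5.0, R0=2200.0, kappa=0.012,
                             J_secr=6.9525e-3)


class TestAqueousDrainage:
    def test_trabecular_baseline(self, aqueous):
        _, j = trabecular_outflow(14.9662, 7.82104, aqueous)
        assert j == pytest.approx(2.9913e-3, rel=1e-4)
        assert round(j, 3) == 0.003

    def test_trabecular_resistance_law(self, aqueous):
        r, j = trabecular_outflow(17.82104, 7.82104, aqueous)
        assert r == pytest.approx(2200.0 * 1.12, rel=1e-12)  # dP = 10 mmHg
        assert j == pytest.approx(10.0 / 2464.0, rel=1e-12)

    def test_trabecular_vanishes_at_equal_pressures(self, aqueous):
        _, j = trabecular_outflow(9.0, 9.0, aqueous)
        assert j == 0.0

    def test_uveoscleral_baseline(self, aqueous):
        _, j = uveoscleral_outflow(14.9662, aqueous)
        assert j == pytest.approx(2.9983e-4, rel=1e-4)

    def test_uveoscleral_limits(self, aqueous):
        assert uveoscleral_outflow(0.0, aqueous)[1] == 0.0
        _, j_half = uveoscleral_outflow(aqueous.k2, aqueous)
        assert j_half == pytest.approx(aqueous.k1 / 2.0, rel=1e-12)
        _, j_big = uveoscleral_outflow(1e6, aqueous)
        assert j_big < aqueous.k1
        assert j_big == pytest.approx(aqueous.k1, rel=1e-4)


class TestTransmuralPressures:
    def test_printed_baseline_values(self):
        state = PressureState.from_mapping(REFERENCE.pressures)
        t = transmural_pressures(state, P_LC=0.0)
        # open ciliary venule at baseline
        assert t.dp_cl_v == pytest.approx(17.118 - 14.9662, rel=1e-10)
        assert t.dp_cl_v > 0
        # translaminar vein segment: midpoint of flanking nodes minus the
        # (zero) lamina stress
        assert t.dp_crv[1] == pytest.approx((19.8107 + 19.7729) / 2,
                                            rel=1e-10)
        # retrobulbar artery segment loaded by extraventricular CSF
        assert t.dp_cra[0] == pytest.approx((46.833 + 43.9041) / 2 - 11.0119,
                                            rel=1e-10)

    def test_equal_flanking_pressures_give_that_pressure(self):
        d = dict(REFERENCE.pressures)
        d["P_crv_2"] = d["P_crv_3"] = 19.5
        t = transmural_pressures(PressureState.from_mapping(d), P_LC=0.0)
        assert t.dp_crv[1] == pytest.approx(19.5, rel=1e-12)

    def test_last_arterial_segment_literal_vs_midpoint(self):
        state = PressureState.from_mapping(REFERENCE.pressures)
        literal = transmural_pressures(state, 0.0, cra4_midpoint=False)
        midpoint = transmural_pressures(state, 0.0, cra4_midpoint=True)
        assert literal.dp_cra[3] == pytest.approx(40.2141 - 14.9662, 1e-10)
        assert midpoint.dp_cra[3] == pytest.approx(
            0.5 * (40.8465 + 40.2141) - 14.9662, 1e-10)


class TestSegmentedVessels:
    def test_zero_transmural_pressure_gives_poiseuille(self, params):
        for vessel in (params.cra, params.crv):
            for n in (1, 2, 3, 4):
                geom = VesselGeometry(A=vessel.A, L=vessel.lengths[n - 1])
                alpha = poiseuille_resistance(vessel.fluid, geom)
                assert cra_crv_segment_resistance(n, 0.0, vessel) == \
                    pytest.approx(alpha, rel=1e-12)

    def test_artery_has_no_collapse_branch(self, params):
        # the artery follows the distension form for all transmural
        # pressures, so a (non-physical) negative loading softens rather
        # than stiffens it
        r_neg = cra_crv_segment_resistance(1, -5.0, params.cra)
        r_zero = cra_crv_segment_resistance(1, 0.0, params.cra)
        assert r_neg > r_zero  # distension form: (1 + dp/kpkL)^-4 grows
        seg = params.cra.segment(1)
        expected = seg.alpha * (1 - 5.0 / (seg.k_p * seg.k_L)) ** -4
        assert r_neg == pytest.approx(expected, rel=1e-12)

    def test_vein_collapse_branch(self, params):
        seg = params.crv.segment(2)
        r = cra_crv_segment_resistance(2, -3.0, params.crv)
        assert r == pytest.approx(
            seg.alpha * (1 + 3.0 / seg.k_p) ** (4.0 / 3.0), rel=1e-12)

    def test_unknown_segment_index(self, params):
        with pytest.raises(InvalidParameterError):
            cra_crv_segment_resistance(5, 0.0, params.cra)


def test_viscosity_unit_round_trip():
    mu_s = 2.12e-5
    assert viscosity_mmhg_min_to_mmhg_s(
        viscosity_mmhg_s_to_mmhg_min(mu_s)) == mu_s
    fluid = FluidProperties.from_mmhg_s(mu_s)
    assert fluid.mu_mmhg_s == pytest.approx(mu_s, rel=1e-15)
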