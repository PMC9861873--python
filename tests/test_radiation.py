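import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tppsim import radiation as rad

SIGMA = rad.SIGMA


def make_geom(**kw):
    base = dict(r_hs=0.1, r_shell=0.1, x_max=0.3, x_min=5e-5, T_hs=1200.0)
    base.update(kw)
    return rad.ExposureGeometry(**base)


class TestDistance:
    def test_start_at_x_max_in_every_mode(self):
        for mode, v in (("static", 0.0), ("enter", 1e-3), ("enter_exit_hold", 1e-3)):
            g = make_geom(trajectory_mode=mode, v=v)
            assert rad.distance_at(0.0, g) == pytest.approx(0.3)

    def test_enter_reaches_and_holds_x_min(self):
        g = make_geom(trajectory_mode="enter", v=1e-3)
        t_arr = (g.x_max - g.x_min) / g.v
        assert rad.distance_at(t_arr, g) == pytest.approx(g.x_min)
        assert rad.distance_at(2 * t_arr, g) == pytest.approx(g.x_min)

    def test_enter_exit_hold_returns_then_holds(self):
        g = make_geom(trajectory_mode="enter_exit_hold", v=1e-3)
        t_arr = (g.x_max - g.x_min) / g.v
        assert rad.distance_at(2 * t_arr, g) == pytest.approx(g.x_max)
        assert rad.distance_at(3 * t_arr, g) == pytest.approx(g.x_max)
        # mid-retreat is between the extremes
        mid = rad.distance_at(1.5 * t_arr, g)
        assert g.x_min < mid < g.x_max

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rad.distance_at(-1.0, make_geom())


def view_factor_quadrature(d, r1, r2, n=80):
    """Independent double-area-integration oracle for coaxial discs.

    F = (2 d^2 / (pi r1^2)) * int over rho1, rho2, phi of
    rho1 rho2 / s^4, with s^2 = d^2 + rho1^2 + rho2^2 - 2 rho1 rho2 cos phi.
    """
    x1, w1 = np.polynomial.legendre.leggauss(n)
    rho1 = 0.5 * r1 * (x1 + 1.0)
    wr1 = 0.5 * r1 * w1
    rho2 = 0.5 * r2 * (x1 + 1.0)
    wr2 = 0.5 * r2 * w1
    phi = 0.5 * (x1 + 1.0) * 2.0 * math.pi
    wphi = 0.5 * w1 * 2.0 * math.pi
    R1, R2, P = np.meshgrid(rho1, rho2, phi, indexing="ij")
    s2 = d * d + R1 * R1 + R2 * R2 - 2.0 * R1 * R2 * np.cos(P)
    integrand = R1 * R2 / s2**2
    W = (
        wr1[:, None, None] * wr2[None, :, None] * wphi[None, None, :]
    )
    total = float(np.sum(integrand * W))
    return 2.0 * d * d / (math.pi * r1 * r1) * total


class TestViewFactor:
    def test_far_field_vanishes(self):
        assert rad.view_factor_coaxial_disks(1e6, 0.1, 0.1) < 1e-10

    def test_contact_limit_equal_radii(self):
        assert rad.view_factor_coaxial_disks(1e-9, 0.1, 0.1) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_closed_form_matches_integration_oracle(self, rng):
        """Closed form vs brute-force double-area integration, < 0.5 %."""
        for _ in range(10):
            d = rng.uniform(0.02, 0.5)
            r1 = rng.uniform(0.05, 0.4)
            r2 = rng.uniform(0.05, 0.4)
            F = rad.view_factor_coaxial_disks(d, r1, r2)
            F_num = view_factor_quadrature(d, r1, r2)
            assert F == pytest.approx(F_num, rel=5e-3)

    def test_strictly_decreasing_in_distance(self):
        ds = np.linspace(0.01, 2.0, 100)
        F = [rad.view_factor_coaxial_disks(d, 0.15, 0.1) for d in ds]
        assert (np.diff(F) < 0).all()
        assert all(0.0 <= f <= 1.0 for f in F)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            rad.view_factor_coaxial_disks(0.0, 0.1, 0.1)


class TestReciprocityComplement:
    @pytest.mark.parametrize(
        "F, A_fab, A_hs, expected",
        [
            (0.0, 1.0, 2.0, (0.0, 1.0)),
            (0.5, 1.0, 1.0, (0.5, 0.5)),
            (0.2, 2.0, 1.0, (0.4, 0.8)),
        ],
    )
    def test_values(self, F, A_fab, A_hs, expected):
        assert rad.reciprocity_and_complement(F, A_fab, A_hs) == pytest.approx(
            expected
        )

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError):
            rad.reciprocity_and_complement(0.9, 10.0, 1.0)

    @given(
        F=st.floats(0.0, 1.0),
        d=st.floats(0.01, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_closure_and_reciprocity_exact(self, F, d):
        """F_shell_hs + F_shell_amb = 1 and A_fab F_shell_hs = A_hs F_hs_shell
        to machine precision."""
        A_fab, A_hs = math.pi * 0.1**2, math.pi * 0.15**2
        if F * A_fab / A_hs > 1.0:
            return
        F_hs, F_amb = rad.reciprocity_and_complement(F, A_fab, A_hs)
        assert F + F_amb == pytest.approx(1.0, abs=1e-15)
        assert A_fab * F == pytest.approx(A_hs * F_hs, rel=1e-13, abs=1e-300)


class TestIncidentRadiation:
    def test_balanced_emission_gives_zero(self):
        g = make_geom(eps_hs=0.9, eps_shell=0.9, T_hs=500.0)
        q = rad.incident_radiation(500.0, 500.0, 500.0, 0.3, 0.7, g)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_no_view_no_excess_gives_zero(self):
        g = make_geom()
        assert rad.incident_radiation(1200.0, 300.0, 300.0, 0.0, 1.0, g) == 0.0

    def test_hand_evaluated_case(self):
        # independent scalar arithmetic: F_hs_shell=0.05, A_hs/A_fab=2,
        # T=(1200, 400, 300), eps=(0.9, 0.1, 0.85) -> 9775.04 W/m^2
        g = rad.ExposureGeometry(
            r_hs=0.1, r_shell=0.1 / math.sqrt(2.0),
            x_max=0.3, x_min=5e-5, T_hs=1200.0,
            eps_hs=0.9, eps_g=0.1, eps_shell=0.85,
        )
        q = rad.incident_radiation(1200.0, 400.0, 300.0, 0.05, 0.9, g)
        assert q == pytest.approx(9775.037475, rel=1e-6)

    def test_net_loss_possible(self):
        g = make_geom()
        q = rad.incident_radiation(301.0, 900.0, 300.0, 0.1, 0.9, g)
        assert q < 0.0


class TestBeer:
    def test_surface_and_transparent_limits(self):
        assert rad.beer_transmitted(1000.0, 500.0, 0.0) == 1000.0
        assert rad.beer_transmitted(1000.0, 0.0, 0.5) == 1000.0

    def test_e_folding_value(self):
        assert rad.beer_transmitted(1000.0, 1000.0, 0.001) == pytest.approx(
            367.879441, rel=1e-8
        )

    @given(
        q=st.floats(0.0, 1e5),
        gamma=st.floats(0.0, 1e4),
        x=st.floats(0.0, 0.01),
    )
    @settings(max_examples=100, deadline=None)
    def test_split_conserves_energy(self, q, gamma, x):
        trans = rad.beer_transmitted(q, gamma, x)
        absd = rad.beer_absorbed(q, gamma, x)
        assert trans + absd == pytest.approx(q, rel=1e-12, abs=1e-9)


class TestNaturalConvection:
    def test_zero_buoyancy_reduces_to_conduction_limit(self):
        conv = rad.ConvectionModel()
        h = rad.natural_convection_h(300.0, 300.0, conv)
        from tppsim.materials import k_air

        assert h == pytest.approx(0.68 * k_air(300.0) / 0.1, rel=1e-12)

    def test_hand_evaluated_laminar_case(self):
        # film at 350 K: beta=1/350, nu=1.589e-5*(350/300)^1.7, a=nu/0.707
        # -> Ra=4.6468e6, Nu=24.5445, h=7.21608 (independent arithmetic)
        conv = rad.ConvectionModel()
        h = rad.natural_convection_h(400.0, 300.0, conv)
        assert h == pytest.approx(7.216080, rel=1e-5)

    def test_monotone_in_temperature_difference(self):
        conv = rad.ConvectionModel()
        hs = [rad.natural_convection_h(300.0 + dT, 300.0, conv)
              for dT in np.linspace(0.0, 600.0, 40)]
        assert (np.diff(hs) >= 0).all()

    def test_turbulent_branch_is_squared_form(self):
        # pin film properties so Ra is controlled and exceeds 1e9
        conv = rad.ConvectionModel(beta=1e-3, a=1e-7, nu=1e-7, Pr=0.707)
        dT = 20.0  # Ra = 9.81*1e-3*20*1e-3/1e-14 = 1.962e10 > 1e9
        Ra = 9.81 * 1e-3 * dT * 0.1**3 / 1e-14
        phi = (1 + (0.492 / 0.707) ** (9 / 16)) ** (8 / 27)
        Nu = (0.825 + 0.387 * Ra ** (1 / 6) / phi) ** 2
        from tppsim.materials import k_air

        expected = Nu * k_air(310.0) / 0.1
        got = rad.natural_convection_h(320.0, 300.0, conv)
        assert got == pytest.approx(expected, rel=1e-10)


class TestGapRadiation:
    def test_equal_temperatures_give_zero(self):
        gm = rad.GapRadiationModel()
        assert rad.gap_radiative_flux(350.0, 350.0, gm) == 0.0

    def test_black_plates_limit(self):
        gm = rad.GapRadiationModel(eps_therm=1.0, eps_skin=1.0, F_therm_skin=1.0)
        q = rad.gap_radiative_flux(400.0, 310.0, gm)
        assert q == pytest.approx(SIGMA * (400.0**4 - 310.0**4), rel=1e-12)

    def test_resistance_network_value(self):
        # eps=(0.9, 0.95), F=1, T=(400, 310) -> 797.327 (scalar oracle)
        gm = rad.GapRadiationModel(eps_therm=0.9, eps_skin=0.95, F_therm_skin=1.0)
        assert rad.gap_radiative_flux(400.0, 310.0, gm) == pytest.approx(
            797.327108, rel=1e-6
        )

    def test_sign_follows_temperature_difference(self):
        gm = rad.GapRadiationModel()
        assert rad.gap_radiative_flux(310.0, 400.0, gm) < 0.0

    def test_nonphysical_surface_rejected(self):
        with pytest.raises(ValueError):
            rad.GapRadiationModel(eps_therm=0.0)
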