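import math

import numpy as np
import pytest
from scipy.special import erf

from tppsim import builtin, run_simulation
from tppsim import solver as sv


def random_dd_system(rng, n):
    lower = rng.uniform(-1.0, 1.0, n)
    upper = rng.uniform(-1.0, 1.0, n)
    diag = np.abs(lower) + np.abs(upper) + rng.uniform(1.0, 2.0, n)
    rhs = rng.uniform(-10.0, 10.0, n)
    lower[0] = 0.0
    upper[-1] = 0.0
    return sv.TridiagonalSystem(lower, diag, upper, rhs)


class TestThomas:
    def test_identity_system(self):
        n = 7
        sys = sv.TridiagonalSystem(
            np.zeros(n), np.ones(n), np.zeros(n), np.arange(n, dtype=float)
        )
        assert np.array_equal(sv.thomas_solve(sys), np.arange(n, dtype=float))

    def test_hand_eliminated_3x3(self):
        # [2 1 0; 1 3 1; 0 1 2] x = [3, 10, 9] -> x = [0.5, 2, 3.5]
        sys = sv.TridiagonalSystem(
            np.array([0.0, 1.0, 1.0]),
            np.array([2.0, 3.0, 2.0]),
            np.array([1.0, 1.0, 0.0]),
            np.array([3.0, 10.0, 9.0]),
        )
        assert np.allclose(sv.thomas_solve(sys), [0.5, 2.0, 3.5], atol=1e-14)

    @pytest.mark.parametrize("n", [8, 400])
    def test_matches_dense_solver(self, rng, n):
        """O(n) elimination agrees with a dense LAPACK solve to 1e-12."""
        sys = random_dd_system(rng, n)
        x = sv.thomas_solve(sys)
        x_ref = np.linalg.solve(sys.to_dense(), sys.rhs)
        assert np.max(np.abs(x - x_ref)) / np.max(np.abs(x_ref)) < 1e-12

    def test_zero_pivot_rejected(self):
        sys = sv.TridiagonalSystem(
            np.zeros(3), np.array([0.0, 1.0, 1.0]), np.zeros(3), np.ones(3)
        )
        with pytest.raises(ValueError):
            sv.thomas_solve(sys)

    def test_nonfinite_rejected(self):
        sys = sv.TridiagonalSystem(
            np.zeros(3), np.array([1.0, np.nan, 1.0]), np.zeros(3), np.ones(3)
        )
        with pytest.raises(ValueError):
            sv.thomas_solve(sys)


class TestCrankNicolsonCore:
    def uniform_slab(self, n=51, k=0.5, rho_cp=1e6, L=0.01):
        h = L / (n - 1)
        C = np.full(n, rho_cp * h)
        C[0] = C[-1] = 0.5 * rho_cp * h
        cond = np.full(n - 1, k / h)
        return C, cond, h

    def test_uniform_field_is_steady(self):
        C, cond, _ = self.uniform_slab()
        T = np.full(C.size, 345.0)
        sys = sv.build_cn_system(C, cond, T, dt=0.5)
        T1 = sv.thomas_solve(sys)
        assert np.allclose(T1, T, atol=1e-12)

    def test_hand_assembled_three_node_system(self):
        """Coefficient-exact match with the hand-written CN matrix for a
        3-node slab with conductance a = k/h and capacity C."""
        C = np.array([1.0, 2.0, 1.0])
        a = 4.0
        cond = np.array([a, a])
        T = np.array([300.0, 310.0, 320.0])
        dt = 0.25
        sys = sv.build_cn_system(C, cond, T, dt)
        assert np.allclose(sys.diag, [C[0] / dt + a / 2,
                                      C[1] / dt + a,
                                      C[2] / dt + a / 2])
        assert np.allclose(sys.lower[1:], [-a / 2, -a / 2])
        assert np.allclose(sys.upper[:-1], [-a / 2, -a / 2])
        rhs0 = (C[0] / dt - a / 2) * T[0] + a / 2 * T[1]
        rhs1 = (C[1] / dt - a) * T[1] + a / 2 * (T[0] + T[2])
        rhs2 = (C[2] / dt - a / 2) * T[2] + a / 2 * T[1]
        assert np.allclose(sys.rhs, [rhs0, rhs1, rhs2])

    def test_energy_conservation_insulated_slab(self, rng):
        """Source-free insulated slab conserves total energy to < 1e-8
        relative over 1000 steps."""
        C, cond, _ = self.uniform_slab(n=41)
        x = np.linspace(0.0, 1.0, 41)
        T = 320.0 + 30.0 * np.sin(3 * math.pi * x) + rng.normal(0, 1, 41)
        E0 = float(np.sum(C * T))
        for _ in range(1000):
            T = sv.thomas_solve(sv.build_cn_system(C, cond, T, dt=0.2))
        drift = abs(float(np.sum(C * T)) - E0) / abs(E0)
        assert drift < 1e-8

    def test_semi_infinite_erf_solution(self):
        """CN + Thomas against the closed-form error-function solution for a
        step surface temperature, < 0.5 % at interior probes."""
        k, rho_cp = 0.5, 2e6
        alpha = k / rho_cp
        L, n = 0.05, 2001
        h = L / (n - 1)
        C = np.full(n, rho_cp * h)
        C[0] = C[-1] = 0.5 * rho_cp * h
        cond = np.full(n - 1, k / h)
        T0, Ts = 300.0, 400.0
        T = np.full(n, T0)
        dt, t_end = 0.05, 50.0
        for _ in range(int(t_end / dt)):
            sys = sv.build_cn_system(C, cond, T, dt, dirichlet_front=Ts)
            T = sv.thomas_solve(sys)
        x = np.linspace(0.0, L, n)
        exact = Ts + (T0 - Ts) * erf(x / (2.0 * math.sqrt(alpha * t_end)))
        probes = (x > 0.0005) & (x < 0.02)  # interior, still semi-infinite
        rel = np.abs(T[probes] - exact[probes]) / (exact[probes] - 0.0)
        assert np.max(np.abs(T[probes] - exact[probes]) / (Ts - T0)) < 5e-3

    def test_second_order_in_time(self):
        """Halving dt reduces the error of a decaying eigenmode by ~4x."""
        k, rho_cp, L, n = 0.5, 2e6, 0.01, 101
        h = L / (n - 1)
        C = np.full(n, rho_cp * h)
        C[0] = C[-1] = 0.5 * rho_cp * h
        cond = np.full(n - 1, k / h)
        x = np.linspace(0.0, L, n)
        alpha = k / rho_cp
        lam = math.pi / L
        T_init = 300.0 + 20.0 * np.cos(lam * x)  # insulated-end eigenmode
        t_end = 40.0

        def run(dt):
            T = T_init.copy()
            for _ in range(int(round(t_end / dt))):
                T = sv.thomas_solve(sv.build_cn_system(C, cond, T, dt))
            return T

        # self-referenced Richardson comparison: the fine-dt run removes the
        # (dt-independent) spatial discretization error from the measurement
        ref = run(0.25)
        e1 = np.max(np.abs(run(4.0) - ref))
        e2 = np.max(np.abs(run(2.0) - ref))
        assert 3.0 < e1 / e2 < 5.0


class TestCoupledAdvance:
    def test_zero_duration_echoes_initial_condition(self):
        scn = builtin("lowlevel_stationary")
        scn.duration = 0.0
        res = run_simulation(scn)
        assert len(res.frames) == 1
        row = res.frames.iloc[0]
        assert row["T_shell_surface"] == 300.0
        assert row["T_liner_back"] == 300.0
        assert row["T_epidermis_surface"] == pytest.approx(305.65)
        # linear initial profile: 305.65 at the surface to 306.65 at the
        # subcutaneous back, so the dermis-subcutaneous interface starts at
        # 305.65 + (0.08 + 2) / 12.08 mm of the 1 K span
        assert row["T_dermis_subcutaneous"] == pytest.approx(
            305.65 + 0.00208 / 0.01208, abs=1e-9
        )
        assert math.isnan(res.burn_times["second_degree"])

    def test_initial_skin_flux_is_negative(self):
        """The skin starts warmer than the liner, so the microenvironment
        initially carries heat out of the skin."""
        scn = builtin("lowlevel_stationary")
        scn.duration = 2.0
        res = run_simulation(scn)
        assert (res.frames["q_skin_total"].iloc[1:10] < 0.0).all()

    def test_static_and_zero_amplitude_runs_bit_identical(self):
        from tppsim.gap import GapMotion

        scn_a = builtin("lowlevel_stationary")
        scn_a.duration = 5.0
        scn_b = builtin("lowlevel_stationary")
        scn_b.duration = 5.0
        # moving-mesh code path with zero amplitude at a nonzero frequency
        scn_b.gap_motion = GapMotion(x0=0.003, amplitude=0.0, frequency=0.5)
        res_a = run_simulation(scn_a)
        res_b = run_simulation(scn_b)
        assert np.array_equal(
            res_a.frames.to_numpy(), res_b.frames.to_numpy()
        )

    def test_unconditional_stability_at_one_second_step(self):
        scn = builtin("lowlevel_stationary")
        scn.dt = 1.0
        scn.duration = 60.0
        res = run_simulation(scn)  # must not diverge
        T = res.frames["T_shell_surface"].to_numpy()
        assert np.isfinite(T).all()
        # no oscillatory blow-up: late-time shell trace is smooth and rising
        late = T[20:]
        assert (np.abs(np.diff(late)) < 10.0).all()

    def test_deep_node_pinned_at_basal_temperature(self):
        scn = builtin("lowlevel_stationary")
        scn.duration = 5.0
        sim = sv.Simulation(scn)
        sim.run()
        assert sim.state.T[-1] == pytest.approx(306.65, abs=1e-9)

    def test_divergence_guard_raises(self):
        scn = builtin("lowlevel_stationary")
        state = sv._initial_state(scn)
        state.T[0] = 1e5
        with pytest.raises(FloatingPointError):
            state.check()
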