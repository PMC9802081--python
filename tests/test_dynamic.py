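"""Dynamic-soaring EOM, transcription, and solver behaviour.

The heavier acceptance-level solves (species orderings, wind sweeps,
convergence) live in test_acceptance; here the machinery itself is
verified against analytic oracles and one small shared solve.
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from paleosoar.dynamic import (
    DynSoarProblem,
    Transcription,
    energy_audit,
    eom_rhs,
    initial_guess,
    solve,
    sweep,
    wingtip_clearance,
)
from paleosoar.synthetic import gen_fixture_trajectories
from paleosoar.wind import WindModel

STILL_AIR = WindModel("sigmoidal", Wmax=0.0, hw=3.0, delta=7 / 6)
SIGMOID = WindModel("sigmoidal", Wmax=10.0, hw=3.0, delta=7 / 6)


@pytest.fixture(scope="module")
def albatross_min_wind(albatross):
    """One shared minimum-wind solve (sigmoidal hw=3 m, delta=7/6 m)."""
    prob = DynSoarProblem(
        morph=albatross, wind=SIGMOID, objective="min_wind", multistart=3, seed=1
    )
    return solve(prob)


class TestEomRhs:
    def test_equilibrium_glide_zero_rates(self, albatross, env):
        glide = gen_fixture_trajectories(albatross, env)[0]
        state = glide.nodes()
        dx, dy, dz, dgamma, dpsi, dV = eom_rhs(state, glide.CL, albatross, STILL_AIR, env)
        assert np.abs(dV).max() < 1e-10
        assert np.abs(dgamma).max() < 1e-10

    def test_helix_turn_rate(self, albatross, env):
        helix = gen_fixture_trajectories(albatross, env)[1]
        state = helix.nodes()
        rates = eom_rhs(state, helix.CL, albatross, STILL_AIR, env)
        psidot = 2 * math.pi / helix.tau
        assert np.allclose(rates[4], psidot, atol=1e-10)
        assert np.abs(rates[5]).max() < 1e-10

    def test_energy_rate_identity_along_integrated_path(self, albatross, env):
        """d/dt(V^2/2 + g z) = -D V/m + W'(z) zdot V cos(gamma) sin(psi),
        cross-checked by finite differences along an integrated trajectory
        in a sheared wind."""
        CL = 1.0
        wind = SIGMOID

        def rhs(t, s):
            state = dict(zip(("x", "y", "z", "gamma", "psi", "V", "phi"),
                             list(s) + [0.3]))
            dx, dy, dz, dgamma, dpsi, dV = eom_rhs(state, CL, albatross, wind, env)
            return [dx, dy, dz, dgamma, dpsi, dV]

        s0 = [0.0, 0.0, 8.0, -0.1, 0.6, 16.0, ]
        sol = solve_ivp(rhs, (0.0, 4.0), s0, rtol=1e-10, atol=1e-12, dense_output=True)
        t = np.linspace(0.2, 3.8, 40)
        s = sol.sol(t)
        x, y, z, gamma, psi, V = s
        e = 0.5 * V**2 + env.g * z
        # analytic rate from the EOM terms
        from paleosoar.dynamic import _forces

        L, D = _forces(V, CL, albatross, env)
        dzdt = -V * np.sin(gamma)
        rate = -D * V / albatross.m + wind.gradient(z) * dzdt * V * np.cos(gamma) * np.sin(psi)
        h = 1e-5
        fd = (0.5 * sol.sol(t + h)[5] ** 2 + env.g * sol.sol(t + h)[2]
              - 0.5 * sol.sol(t - h)[5] ** 2 - env.g * sol.sol(t - h)[2]) / (2 * h)
        assert np.allclose(rate, fd, rtol=1e-5, atol=1e-6)


class TestWingtipClearance:
    def test_wings_level_equals_height(self):
        state = {"z": 2.0, "gamma": 0.3, "phi": 0.0}
        assert wingtip_clearance(state, 3.0) == pytest.approx(2.0)

    def test_vertical_pitch_equals_height(self):
        state = {"z": 2.0, "gamma": math.pi / 2, "phi": 1.0}
        assert wingtip_clearance(state, 3.0) == pytest.approx(2.0)

    def test_banked_violation(self):
        state = {"z": 1.0, "gamma": 0.0, "phi": math.radians(45.0)}
        assert wingtip_clearance(state, 3.05) == pytest.approx(-0.078, abs=1e-3)


class TestTranscription:
    def test_variable_counts(self, albatross):
        travel = DynSoarProblem(morph=albatross, wind=SIGMOID,
                                objective="max_travel_speed", fixed_wind_speed=10.0)
        assert Transcription(travel).n_var == 359
        minw = DynSoarProblem(morph=albatross, wind=SIGMOID, objective="min_wind")
        assert Transcription(minw).n_var == 360

    def test_equality_count(self, albatross):
        prob = DynSoarProblem(morph=albatross, wind=SIGMOID, objective="min_wind")
        tr = Transcription(prob)
        z0 = initial_guess(prob, np.random.default_rng(0))
        # 6(N-1) defects + 2 anchors + 5 periodicity conditions
        assert tr.equality(z0).size == 6 * 50 + 7

    def test_glide_fixture_zero_defects(self, albatross, env):
        glide = gen_fixture_trajectories(albatross, env)[0]
        prob = DynSoarProblem(morph=albatross, wind=STILL_AIR,
                              objective="max_travel_speed", fixed_wind_speed=0.0)
        tr = Transcription(prob)
        zv = tr.pack(glide.nodes(), glide.CL, glide.tau)
        eq = tr.equality(zv)
        assert np.abs(eq[: 6 * 50]).max() < 1e-10

    def test_helix_defects_third_order(self, albatross, env):
        """Trapezoidal defects of the exact helix shrink as h^3."""
        norms = []
        for N in (26, 51, 101):
            helix = gen_fixture_trajectories(albatross, env, N=N)[2]
            prob = DynSoarProblem(morph=albatross, wind=STILL_AIR, N=N,
                                  objective="max_travel_speed", fixed_wind_speed=0.0)
            tr = Transcription(prob)
            zv = tr.pack(helix.nodes(), helix.CL, helix.tau)
            norms.append(np.abs(tr.equality(zv)[: 6 * (N - 1)]).max())
        assert norms[0] > norms[1] > norms[2]
        order01 = math.log(norms[0] / norms[1]) / math.log(2.0)
        order12 = math.log(norms[1] / norms[2]) / math.log(2.0)
        assert order01 == pytest.approx(3.0, abs=0.4)
        assert order12 == pytest.approx(3.0, abs=0.4)

    def test_complex_step_jacobian_matches_fd(self, albatross):
        prob = DynSoarProblem(morph=albatross, wind=SIGMOID, objective="min_wind")
        tr = Transcription(prob)
        z0 = initial_guess(prob, np.random.default_rng(4))
        J = tr.equality_jac(z0)
        rng = np.random.default_rng(0)
        h = 1e-6
        for i in rng.integers(0, tr.n_var, size=8):
            e = np.zeros(tr.n_var)
            e[i] = h
            fd = (tr.equality(z0 + e) - tr.equality(z0 - e)) / (2 * h)
            assert np.abs(J[:, i] - fd).max() < 1e-5

    def test_objective_gradient_matches_fd(self, albatross):
        for objective, kw in (("min_wind", {}),
                              ("max_travel_speed", {"fixed_wind_speed": 10.0}),
                              ("max_upwind_speed", {"fixed_wind_speed": 10.0})):
            prob = DynSoarProblem(morph=albatross, wind=SIGMOID,
                                  objective=objective, **kw)
            tr = Transcription(prob)
            z0 = initial_guess(prob, np.random.default_rng(5))
            g = tr.objective_grad(z0)
            h = 1e-7
            rng = np.random.default_rng(1)
            for i in rng.integers(0, tr.n_var, size=6):
                e = np.zeros(tr.n_var)
                e[i] = h
                fd = (tr.objective(z0 + e) - tr.objective(z0 - e)) / (2 * h)
                assert g[i] == pytest.approx(float(fd), abs=1e-6)

    def test_invalid_problem_configs(self, albatross):
        with pytest.raises(ValueError):
            DynSoarProblem(morph=albatross, wind=SIGMOID, objective="fly_fast")
        with pytest.raises(ValueError):
            DynSoarProblem(morph=albatross, wind=SIGMOID,
                           objective="max_travel_speed")  # no wind speed
        with pytest.raises(ValueError):
            DynSoarProblem(morph=albatross, wind=SIGMOID, N=5)


class TestSolve:
    def test_min_wind_positive_and_feasible(self, albatross_min_wind):
        sol = albatross_min_wind
        assert sol.feasible
        # no periodic nonpowered cycle exists without shear
        assert sol.objective_value > 0.5
        assert sol.objective_value < 10.0
        assert sol.max_constraint_violation < 1e-6

    def test_solution_respects_path_constraints(self, albatross_min_wind, albatross):
        sol = albatross_min_wind
        assert sol.z.min() >= 0.5 - 1e-6
        tip = sol.z - 0.5 * albatross.b * np.abs(np.sin(sol.phi)) * np.cos(sol.gamma)
        assert tip.min() >= -1e-6
        env = sol.problem.env
        load = 0.5 * env.rho * sol.CL * albatross.Sw * sol.V**2 / (albatross.m * env.g)
        assert load.max() <= 3.0 + 1e-6
        assert sol.CL <= albatross.CLmax + 1e-9

    def test_energy_audit_balances(self, albatross_min_wind):
        drag, shear = energy_audit(albatross_min_wind)
        assert drag > 0
        assert abs(drag - shear) / drag < 0.01

    def test_periodicity(self, albatross_min_wind):
        sol = albatross_min_wind
        for key in ("z", "gamma", "psi", "V", "phi"):
            arr = getattr(sol, key)
            assert arr[0] == pytest.approx(arr[-1], abs=1e-5)

    def test_determinism_same_seed(self, albatross):
        prob = DynSoarProblem(morph=albatross, wind=SIGMOID, objective="min_wind",
                              N=21, multistart=2, seed=7)
        a = solve(prob)
        b = solve(prob)
        assert a.feasible and b.feasible
        assert a.objective_value == b.objective_value
        assert np.array_equal(a.zvec, b.zvec)

    def test_warm_start_across_meshes(self, albatross_min_wind, albatross):
        """A coarse solution interpolated onto a finer mesh stays feasible
        after a short polish."""
        prob = replace(albatross_min_wind.problem, N=61, multistart=0)
        sol = solve(prob, warm_start=albatross_min_wind)
        assert sol.feasible
        assert sol.objective_value == pytest.approx(
            albatross_min_wind.objective_value, rel=0.02
        )


def test_sweep_schema_and_truncation(reg):
    """Small sweep on a coarse mesh: Wmin row plus speed series per wind."""
    petrel = reg["white_chinned_petrel"]
    wm = WindModel("sigmoidal", Wmax=10.0, hw=1.0, delta=3 / 6)
    df = sweep([petrel], wm, N=21, multistart=2, seed=0, wind_step=0.5,
               wind_upper=None, maxiter=300)
    wmin_rows = df[df["quantity"] == "Wmin"]
    assert len(wmin_rows) == 1
    wmin = float(wmin_rows["value"].iloc[0])
    assert math.isfinite(wmin)
    travel = df[df["quantity"] == "max_travel_speed"].sort_values("wind_speed")
    assert len(travel) >= 1
    assert travel["wind_speed"].iloc[0] == pytest.approx(wmin)
    # grid upper bound equals the max species Wmin + 2
    assert travel["wind_speed"].iloc[-1] <= wmin + 2.0 + 1e-9
    # series truncates after the first wind exceeding 40 m/s
    vals = travel["value"].to_numpy()
    over = np.where(vals > 40.0)[0]
    if over.size:
        assert over[0] == len(vals) - 1
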