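"""Periodic dynamic-soaring trajectory optimization.

A soaring animal over the sea is modelled as a point mass in a steady,
height-dependent horizontal wind W(z) blowing along -y.  With airspeed V,
pitch gamma (positive nose-down), yaw psi, and bank phi, the equations of
motion are

    m dV/dt      = -D + m g sin(gamma) + m W'(z) dz/dt cos(gamma) sin(psi)
    m V dgamma/dt = L cos(phi) - m g cos(gamma) + m W'(z) dz/dt sin(gamma) sin(psi)
    m V cos(gamma) dpsi/dt = L sin(phi) + m W'(z) dz/dt cos(psi)
    dx/dt = V cos(gamma) cos(psi)
    dy/dt = V cos(gamma) sin(psi) - W(z)
    dz/dt = -V sin(gamma)

with L = (rho/2) CL Sw V^2 and D = (rho/2) (CDpro(CL) + 0.01 + k CL^2/(pi Ra)) Sw V^2.
The lift coefficient is held constant over a cycle; the bank angle is the
time-varying control.

The periodic optimal-control problem (periodic in z, gamma, psi, phi, V;
load factor L/mg <= 3; wingtip clearance z - (b/2)|sin phi| cos gamma >= 0;
z >= 0.5 m) is transcribed by trapezoidal direct collocation on N nodes with
free cycle period tau and solved with SQP (SLSQP) from multiple randomized
initial cycles.  Three objectives are supported: the minimum wind-profile
parameter (W10 or Wmax) sustaining a periodic cycle, the maximum
cycle-averaged travel speed sqrt(x_N^2+y_N^2)/tau, and the maximum
cycle-averaged upwind speed y_N/tau.

Constraint Jacobians are exact to machine precision via batched complex-step
differentiation, which is what makes N = 51 problems (359-360 variables)
tractable with a dense SQP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .morphology import Environment, SpeciesMorphology
from .wind import WindModel

__all__ = [
    "DynSoarProblem",
    "DynSoarSolution",
    "Transcription",
    "eom_rhs",
    "wingtip_clearance",
    "energy_audit",
    "initial_guess",
    "solve",
    "sweep",
]

OBJECTIVES = ("min_wind", "max_travel_speed", "max_upwind_speed")

# Variable scaling (SQP conditioning): positions in units of 100 m, speeds
# of 20 m/s, angles of 1 rad, the cycle period of 10 s.
POS_SCALE = 100.0
SPEED_SCALE = 20.0
TAU_SCALE = 10.0

_CS_STEP = 1e-100  # complex-step size; derivatives exact to machine precision


@dataclass(frozen=True)
class DynSoarProblem:
    """One periodic dynamic-soaring optimization instance."""

    morph: SpeciesMorphology
    wind: WindModel
    objective: str = "min_wind"
    N: int = 51
    fixed_wind_speed: float | None = None  # profile parameter for the speed objectives
    load_factor_max: float = 3.0
    z_min: float = 0.5
    z_max: float = 100.0
    multistart: int = 8
    seed: int = 0
    maxiter: int = 500
    wind_param_max: float = 40.0  # m/s upper bound on the free wind parameter
    enforce_wingtip: bool = True
    env: Environment = field(default_factory=Environment)

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.N < 11:
            raise ValueError("need at least 11 collocation nodes")
        if self.objective != "min_wind" and self.fixed_wind_speed is None:
            raise ValueError("speed objectives need fixed_wind_speed")


@dataclass
class DynSoarSolution:
    """Optimized (or failed) periodic cycle."""

    problem: DynSoarProblem
    status: str  # "optimal" | "infeasible"
    objective_value: float  # m/s (wind parameter, travel speed, or upwind speed)
    t: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    z: np.ndarray | None = None
    gamma: np.ndarray | None = None
    psi: np.ndarray | None = None
    V: np.ndarray | None = None
    phi: np.ndarray | None = None
    CL: float = math.nan
    tau: float = math.nan
    wind_param: float = math.nan
    max_constraint_violation: float = math.nan
    energy_residual: float = math.nan  # relative drag-work vs shear-work mismatch
    zvec: np.ndarray | None = None  # scaled decision vector (warm starts)

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"

    def to_dict(self) -> dict:
        d = {
            "species": self.problem.morph.name,
            "wind_model": self.problem.wind.label(),
            "objective": self.problem.objective,
            "status": self.status,
            "objective_value": self.objective_value,
            "CL": self.CL,
            "tau": self.tau,
            "wind_param": self.wind_param,
            "max_constraint_violation": self.max_constraint_violation,
            "energy_residual": self.energy_residual,
        }
        if self.t is not None:
            for key in ("t", "x", "y", "z", "gamma", "psi", "V", "phi"):
                d[key] = list(np.asarray(getattr(self, key), float))
        return d


# --- equations of motion ---------------------------------------------------


def _forces(V, CL, morph: SpeciesMorphology, env: Environment, span_beta=1.0):
    """Lift and drag magnitudes (per Eqs. of the aerodynamic model)."""
    drag = morph.drag
    Sw = span_beta * morph.Sw
    Ra = span_beta * morph.Ra
    q = 0.5 * env.rho * V**2
    L = q * CL * Sw
    cd_pro = drag.profile_drag(CL)
    D = q * Sw * cd_pro + q * morph.Sw * drag.parasite_factor + (
        env.rho * drag.k * CL**2 / (2.0 * math.pi * Ra)
    ) * Sw * V**2
    return L, D


def eom_rhs(state, CL, morph: SpeciesMorphology, wind: WindModel,
            env: Environment | None = None, span_beta: float = 1.0):
    """Time derivatives (dx, dy, dz, dgamma, dpsi, dV) of the point-mass EOM.

    ``state`` is a mapping or tuple (x, y, z, gamma, psi, V, phi); entries may
    be scalars or arrays (broadcast together).  ``span_beta`` scales the wing
    (1 = unreduced wing, the dynamic-soaring setting).
    """
    env = env or Environment()
    if isinstance(state, dict):
        x, y, z, gamma, psi, V, phi = (
            state[k] for k in ("x", "y", "z", "gamma", "psi", "V", "phi")
        )
    else:
        x, y, z, gamma, psi, V, phi = state
    m = morph.m
    W = wind.speed(z)
    Wg = wind.gradient(z)
    L, D = _forces(V, CL, morph, env, span_beta)
    sg, cg = np.sin(gamma), np.cos(gamma)
    sp, cp = np.sin(psi), np.cos(psi)
    dz = -V * sg
    dV = (-D + m * env.g * sg) / m + Wg * dz * cg * sp
    dgamma = (L * np.cos(phi) - m * env.g * cg + m * Wg * dz * sg * sp) / (m * V)
    dpsi = (L * np.sin(phi) + m * Wg * dz * cp) / (m * V * cg)
    dx = V * cg * cp
    dy = V * cg * sp - W
    return dx, dy, dz, dgamma, dpsi, dV


def wingtip_clearance(state, b: float):
    """Height of the lower wingtip above the sea, z - (b/2)|sin phi| cos gamma."""
    if isinstance(state, dict):
        z, gamma, phi = state["z"], state["gamma"], state["phi"]
    else:
        z, gamma, phi = state[2], state[3], state[6]
    return z - 0.5 * b * np.abs(np.sin(phi)) * np.cos(gamma)


# --- transcription ---------------------------------------------------------


class Transcription:
    """Trapezoidal direct collocation of a :class:`DynSoarProblem`.

    Decision vector (scaled): the 7 per-node states/controls in blocks
    [x, y, z, gamma, psi, V, phi] (N each), then CL, tau, and — for the
    minimum-wind objective — the wind-profile parameter: 7N+2 or 7N+3
    variables.  Equalities: 6(N-1) trapezoidal defects, the start anchor
    x1 = y1 = 0, and the five periodicity conditions (z, gamma, psi, phi, V).
    Inequalities (g >= 0): load factor L/mg <= limit at every node and the
    wingtip-clearance pair z -/+ (b/2) sin(phi) cos(gamma) >= 0 (the pair is
    the smooth equivalent of the |sin phi| constraint).
    """

    def __init__(self, problem: DynSoarProblem):
        self.problem = problem
        N = problem.N
        self.N = N
        self.n_var = 7 * N + 2 + (1 if problem.objective == "min_wind" else 0)
        self._blocks = {
            name: slice(i * N, (i + 1) * N)
            for i, name in enumerate(["x", "y", "z", "gamma", "psi", "V", "phi"])
        }
        self.i_CL = 7 * N
        self.i_tau = 7 * N + 1
        self.i_wind = 7 * N + 2 if problem.objective == "min_wind" else None
        self._state_scale = np.array(
            [POS_SCALE, POS_SCALE, POS_SCALE, 1.0, 1.0, SPEED_SCALE], dtype=float
        )

    # -- packing ------------------------------------------------------------

    def pack(self, nodes: dict, CL: float, tau: float, wind_param: float | None = None):
        zvec = np.empty(self.n_var)
        for name, sl in self._blocks.items():
            scale = POS_SCALE if name in ("x", "y", "z") else (
                SPEED_SCALE if name == "V" else 1.0
            )
            zvec[sl] = np.asarray(nodes[name], float) / scale
        zvec[self.i_CL] = CL
        zvec[self.i_tau] = tau / TAU_SCALE
        if self.i_wind is not None:
            if wind_param is None:
                raise ValueError("min_wind transcription needs a wind parameter")
            zvec[self.i_wind] = wind_param / SPEED_SCALE
        return zvec

    def unpack(self, zvec):
        zvec = np.asarray(zvec)
        out = {}
        for name, sl in self._blocks.items():
            scale = POS_SCALE if name in ("x", "y", "z") else (
                SPEED_SCALE if name == "V" else 1.0
            )
            out[name] = zvec[..., sl] * scale
        out["CL"] = zvec[..., self.i_CL]
        out["tau"] = zvec[..., self.i_tau] * TAU_SCALE
        if self.i_wind is not None:
            out["wind_param"] = zvec[..., self.i_wind] * SPEED_SCALE
        else:
            out["wind_param"] = self.problem.fixed_wind_speed
        return out

    # -- dynamics on the node arrays ----------------------------------------

    def _rhs(self, u):
        """Stacked state derivative f(s) with shape (..., 6, N)."""
        p = self.problem
        wind = p.wind
        z, gamma, psi, V, phi = u["z"], u["gamma"], u["psi"], u["V"], u["phi"]
        CL = u["CL"][..., None] if np.ndim(u["CL"]) else u["CL"]
        wp = u["wind_param"]
        if np.ndim(wp):
            wp = wp[..., None]
        W = wp * wind.shape(z)
        Wg = wp * wind.shape_gradient(z)
        m, env = p.morph.m, p.env
        L, D = _forces(V, CL, p.morph, env)
        sg, cg = np.sin(gamma), np.cos(gamma)
        sp, cp = np.sin(psi), np.cos(psi)
        dz = -V * sg
        dV = (-D + m * env.g * sg) / m + Wg * dz * cg * sp
        dgamma = (L * np.cos(phi) - m * env.g * cg + m * Wg * dz * sg * sp) / (m * V)
        dpsi = (L * np.sin(phi) + m * Wg * dz * cp) / (m * V * cg)
        dx = V * cg * cp
        dy = V * cg * sp - W
        return np.stack([dx, dy, dz, dgamma, dpsi, dV], axis=-2)

    def equality(self, zvec):
        """Scaled equality-constraint vector (defects, anchor, periodicity)."""
        u = self.unpack(zvec)
        s = np.stack([u[k] for k in ("x", "y", "z", "gamma", "psi", "V")], axis=-2)
        f = self._rhs(u)
        tau = u["tau"]
        h = (tau[..., None, None] if np.ndim(tau) else tau) / (self.N - 1)
        defects = s[..., 1:] - s[..., :-1] - 0.5 * h * (f[..., 1:] + f[..., :-1])
        defects = defects / self._state_scale[:, None]
        anchor = np.stack([u["x"][..., 0], u["y"][..., 0]], axis=-1) / POS_SCALE
        per = np.stack(
            [
                (u["z"][..., 0] - u["z"][..., -1]) / POS_SCALE,
                u["gamma"][..., 0] - u["gamma"][..., -1],
                u["psi"][..., 0] - u["psi"][..., -1],
                u["phi"][..., 0] - u["phi"][..., -1],
                (u["V"][..., 0] - u["V"][..., -1]) / SPEED_SCALE,
            ],
            axis=-1,
        )
        lead = defects.shape[:-2]
        return np.concatenate(
            [defects.reshape(lead + (-1,)), anchor, per], axis=-1
        )

    def inequality(self, zvec):
        """Scaled inequality vector, feasible when every entry >= 0."""
        p = self.problem
        u = self.unpack(zvec)
        V, z, gamma, phi = u["V"], u["z"], u["gamma"], u["phi"]
        CL = u["CL"][..., None] if np.ndim(u["CL"]) else u["CL"]
        env = p.env
        mg = p.morph.m * env.g
        load = 0.5 * env.rho * CL * p.morph.Sw * V**2 / mg
        parts = [p.load_factor_max - load]
        if p.enforce_wingtip:
            tip = 0.5 * p.morph.b * np.sin(phi) * np.cos(gamma)
            parts.append((z - tip) / 10.0)
            parts.append((z + tip) / 10.0)
        return np.concatenate(parts, axis=-1)

    def objective(self, zvec):
        p = self.problem
        u = self.unpack(zvec)
        tau = u["tau"]
        if p.objective == "min_wind":
            return u["wind_param"] / SPEED_SCALE
        xN, yN = u["x"][..., -1], u["y"][..., -1]
        if p.objective == "max_travel_speed":
            return -np.sqrt(xN**2 + yN**2) / tau / SPEED_SCALE
        return -yN / tau / SPEED_SCALE

    # -- complex-step derivatives -------------------------------------------

    def _jac(self, fun, zvec):
        n = self.n_var
        zb = np.asarray(zvec, float)[None, :] + 1j * _CS_STEP * np.eye(n)
        return np.imag(fun(zb)).T / _CS_STEP  # (m, n)

    def equality_jac(self, zvec):
        return self._jac(self.equality, zvec)

    def inequality_jac(self, zvec):
        return self._jac(self.inequality, zvec)

    def objective_grad(self, zvec):
        """Analytic gradient (the objectives touch few variables)."""
        p = self.problem
        g = np.zeros(self.n_var)
        if p.objective == "min_wind":
            g[self.i_wind] = 1.0
            return g
        zvec = np.asarray(zvec, float)
        N = self.N
        ix, iy = self._blocks["x"].start + N - 1, self._blocks["y"].start + N - 1
        zx, zy, zt = zvec[ix], zvec[iy], zvec[self.i_tau]
        # scaled objective: -(POS/ (TAU*SPEED)) * sqrt(zx^2+zy^2)/zt  (or zy/zt)
        c = POS_SCALE / (TAU_SCALE * SPEED_SCALE)
        if p.objective == "max_travel_speed":
            r = math.hypot(zx, zy)
            if r < 1e-12:
                return g
            g[ix] = -c * zx / (r * zt)
            g[iy] = -c * zy / (r * zt)
            g[self.i_tau] = c * r / zt**2
        else:
            g[iy] = -c / zt
            g[self.i_tau] = c * zy / zt**2
        return g

    def pack_solution(self, sol: "DynSoarSolution") -> np.ndarray:
        """Decision vector built from a solution, interpolated in normalized
        cycle time if the node counts differ (warm starts, mesh refinement)."""
        s_old = np.linspace(0.0, 1.0, len(sol.V))
        s_new = np.linspace(0.0, 1.0, self.N)
        nodes = {
            k: np.interp(s_new, s_old, np.asarray(getattr(sol, k), float))
            for k in ("x", "y", "z", "gamma", "psi", "V", "phi")
        }
        wp = sol.wind_param if self.i_wind is not None else None
        return self.pack(nodes, sol.CL, sol.tau, wp)

    # -- bounds and diagnostics ---------------------------------------------

    def bounds(self):
        p = self.problem
        N = self.N
        lo = np.empty(self.n_var)
        hi = np.empty(self.n_var)
        spans = {
            "x": (-3000.0, 3000.0),
            "y": (-3000.0, 3000.0),
            "z": (p.z_min, p.z_max),
            "gamma": (-math.radians(80.0), math.radians(80.0)),
            "psi": (-3.0 * math.pi, 3.0 * math.pi),
            "V": (2.0, 80.0),
            "phi": (-math.radians(85.0), math.radians(85.0)),
        }
        for name, sl in self._blocks.items():
            scale = POS_SCALE if name in ("x", "y", "z") else (
                SPEED_SCALE if name == "V" else 1.0
            )
            lo[sl], hi[sl] = spans[name][0] / scale, spans[name][1] / scale
        lo[self.i_CL], hi[self.i_CL] = 0.01, p.morph.CLmax
        lo[self.i_tau], hi[self.i_tau] = 1.0 / TAU_SCALE, 60.0 / TAU_SCALE
        if self.i_wind is not None:
            lo[self.i_wind], hi[self.i_wind] = 0.0, p.wind_param_max / SPEED_SCALE
        return list(zip(lo, hi))

    def max_violation(self, zvec) -> float:
        eq = np.abs(self.equality(zvec)).max()
        ineq = float(np.maximum(0.0, -self.inequality(zvec)).max(initial=0.0))
        lo, hi = map(np.array, zip(*self.bounds()))
        zb = np.asarray(zvec, float)
        bv = max(np.maximum(lo - zb, 0.0).max(), np.maximum(zb - hi, 0.0).max())
        return float(max(eq, ineq, bv))

    def solution_from(self, zvec, status: str) -> DynSoarSolution:
        p = self.problem
        u = self.unpack(zvec)
        tau = float(u["tau"])
        obj = float(self.objective(zvec))
        value = obj * SPEED_SCALE if p.objective == "min_wind" else -obj * SPEED_SCALE
        sol = DynSoarSolution(
            problem=p,
            status=status,
            objective_value=value,
            t=np.linspace(0.0, tau, self.N),
            x=u["x"],
            y=u["y"],
            z=u["z"],
            gamma=u["gamma"],
            psi=u["psi"],
            V=u["V"],
            phi=u["phi"],
            CL=float(u["CL"]),
            tau=tau,
            wind_param=float(u["wind_param"]),
            max_constraint_violation=self.max_violation(zvec),
            zvec=np.asarray(zvec, float).copy(),
        )
        drag_work, shear_work = energy_audit(sol)
        denom = max(abs(drag_work), 1e-12)
        sol.energy_residual = abs(drag_work - shear_work) / denom
        return sol


def transcribe(problem: DynSoarProblem) -> Transcription:
    return Transcription(problem)


# --- energy bookkeeping ----------------------------------------------------


def energy_audit(sol: DynSoarSolution) -> tuple[float, float]:
    """Integrated specific drag work and shear-energy extraction per cycle [J/kg].

    Along the cycle d/dt(V^2/2 + g z) = -D V / m + W'(z) dz/dt V cos(gamma)
    sin(psi); with V and z periodic the two integrals must balance.
    """
    p = sol.problem
    env = p.env
    wind = p.wind.with_param(sol.wind_param)
    L, D = _forces(sol.V, sol.CL, p.morph, env)
    Wg = wind.gradient(sol.z)
    dz = -sol.V * np.sin(sol.gamma)
    drag_rate = D * sol.V / p.morph.m
    shear_rate = Wg * dz * sol.V * np.cos(sol.gamma) * np.sin(sol.psi)
    drag_work = float(np.trapezoid(drag_rate, sol.t))
    shear_work = float(np.trapezoid(shear_rate, sol.t))
    return drag_work, shear_work


# --- initial guesses -------------------------------------------------------


def initial_guess(problem: DynSoarProblem, rng: np.random.Generator) -> np.ndarray:
    """Inclined elliptical soaring loop: oscillating height, heading, and bank.

    Centre height sits just above the shear layer (sigmoidal) or a few metres
    up (logarithmic); airspeed starts near 1.6x the stall speed; the cycle
    period scales mildly with the stall speed.
    """
    p = problem
    N = p.N
    tr = Transcription(p)
    Vs = p.morph.stall_speed(p.env)
    s = np.linspace(0.0, 1.0, N)
    two_pi_s = 2.0 * math.pi * s

    size = Vs / 11.0  # ~1 for an albatross; >1 for the giants
    amp = rng.uniform(2.0, 4.0 + 0.8 * p.morph.b)
    if p.wind.kind == "sigmoidal":
        zc = p.wind.hw + 2.0
    else:
        zc = 3.0
    zc = max(zc, amp + p.z_min + 0.5 + 0.5 * p.morph.b)
    z = zc - amp * np.cos(two_pi_s)

    V0 = 1.6 * Vs * rng.uniform(0.85, 1.25)
    V = V0 * (1.0 + 0.15 * np.cos(two_pi_s + rng.uniform(0, 2 * math.pi)))
    tau = 6.0 * size * rng.uniform(0.8, 2.2)

    dzdt = amp * 2.0 * math.pi / tau * np.sin(two_pi_s)
    gamma = np.arcsin(np.clip(-dzdt / V, -0.95, 0.95))

    psi_c = rng.uniform(-0.4, 0.4)
    dpsi = rng.uniform(0.6, 1.3)
    psi = psi_c + dpsi * np.cos(two_pi_s + rng.uniform(0, 2 * math.pi))
    phi = rng.uniform(0.3, 1.0) * np.cos(two_pi_s + rng.uniform(0, 2 * math.pi))

    wind_param = (
        p.fixed_wind_speed
        if p.objective != "min_wind"
        else float(min(size * rng.uniform(6.0, 18.0), 0.9 * p.wind_param_max))
    )
    wind = p.wind.with_param(wind_param)
    dt = tau / (N - 1)
    dx = V * np.cos(gamma) * np.cos(psi)
    dy = V * np.cos(gamma) * np.sin(psi) - wind.speed(z)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (dx[1:] + dx[:-1]) * dt)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (dy[1:] + dy[:-1]) * dt)])

    CL = float(np.clip(2.0 * p.morph.m * p.env.g / (p.env.rho * p.morph.Sw * V0**2),
                       0.05, p.morph.CLmax))
    nodes = {"x": x, "y": y, "z": z, "gamma": gamma, "psi": psi, "V": V, "phi": phi}
    return tr.pack(nodes, CL, tau, wind_param if tr.i_wind is not None else None)


# --- solver ----------------------------------------------------------------

FEAS_TOL = 1e-6  # scaled feasibility tolerance for accepting a solution
COARSE_N = 21  # node count of the coarse mesh used to seed cold starts


def _solve_single(tr: Transcription, z0: np.ndarray, maxiter: int):
    cons = [
        {"type": "eq", "fun": tr.equality, "jac": tr.equality_jac},
        {"type": "ineq", "fun": tr.inequality, "jac": tr.inequality_jac},
    ]
    res = minimize(
        tr.objective,
        z0,
        jac=tr.objective_grad,
        bounds=tr.bounds(),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": maxiter, "ftol": 1e-8},
    )
    return res


def _attempt(tr: Transcription, z0: np.ndarray, maxiter: int,
             restarts: int = 2, tol: float = FEAS_TOL):
    """SLSQP with restart polishing: a stalled line search or an iteration
    cap just short of feasibility is usually cured by restarting from the
    incumbent point.  Returns (x, violation) or None."""
    x = np.asarray(z0, float)
    for _ in range(restarts + 1):
        try:
            res = _solve_single(tr, x, maxiter)
        except (ValueError, FloatingPointError):
            return None
        x = res.x
        viol = tr.max_violation(x)
        if res.status == 0 and viol <= tol:
            return x, viol
        if viol > 1e-2:  # collapsed to a degenerate point; restarts won't help
            return None
    viol = tr.max_violation(x)
    if viol <= tol:
        return x, viol
    return None


def solve(problem: DynSoarProblem,
          warm_start: "DynSoarSolution | np.ndarray | None" = None
          ) -> DynSoarSolution:
    """Best feasible local optimum over the multistart set.

    A warm start (a neighbouring solution, or a raw decision vector of
    matching size) is tried first.  Cold starts are randomized elliptical
    loops, pre-converged on a coarse 21-node mesh and interpolated onto the
    working mesh before the full solve.  If no start reaches scaled
    feasibility <= 1e-6 an infeasibility marker is returned, not raised.
    """
    tr = Transcription(problem)
    rng = np.random.default_rng(problem.seed)
    starts: list[np.ndarray] = []
    if isinstance(warm_start, DynSoarSolution):
        if warm_start.feasible:
            starts.append(tr.pack_solution(warm_start))
    elif warm_start is not None:
        ws = np.asarray(warm_start, float)
        if ws.size == tr.n_var:
            starts.append(ws)

    sign = 1.0 if problem.objective == "min_wind" else -1.0
    coarse_tr = None
    if problem.N > COARSE_N + 4 and problem.multistart > 0:
        coarse_tr = Transcription(replace(problem, N=COARSE_N))
    if coarse_tr is None:
        starts += [initial_guess(problem, rng) for _ in range(problem.multistart)]
    else:
        # Pre-converge the cold starts on the coarse mesh; only distinct
        # coarse optima (best three) are refined on the working mesh.
        coarse_objs: list[tuple[float, np.ndarray]] = []
        # failed coarse attempts are cheap, so draw three per requested start
        for _ in range(3 * problem.multistart):
            if len(coarse_objs) >= max(2, problem.multistart):
                break
            z0c = initial_guess(coarse_tr.problem, rng)
            got = _attempt(coarse_tr, z0c, min(problem.maxiter, 300),
                           restarts=1, tol=1e-5)
            if got is None:
                continue
            coarse_objs.append((float(coarse_tr.objective(got[0])), got[0]))
        coarse_objs.sort(key=lambda p: p[0])
        kept: list[tuple[float, np.ndarray]] = []
        for obj, xc in coarse_objs:
            if all(abs(obj - o) > max(5e-4, 5e-3 * abs(o)) for o, _ in kept):
                kept.append((obj, xc))
            if len(kept) == 3:
                break
        for _, xc in kept:
            starts.append(tr.pack_solution(coarse_tr.solution_from(xc, "optimal")))
        if not starts:
            # Nothing survived the coarse stage — usually a genuinely
            # infeasible problem (wind below the minimum required).  One raw
            # cold start on the working mesh guards against coarse-mesh
            # artefacts without spending minutes confirming infeasibility.
            starts.append(initial_guess(problem, rng))

    best: DynSoarSolution | None = None
    for z0 in starts:
        got = _attempt(tr, z0, problem.maxiter)
        if got is None:
            continue
        sol = tr.solution_from(got[0], "optimal")
        if best is None or sign * sol.objective_value < sign * best.objective_value:
            best = sol
    if best is None:
        return DynSoarSolution(problem=problem, status="infeasible",
                               objective_value=math.nan)
    return best


# --- wind-speed sweep ------------------------------------------------------

TRAVEL_SPEED_STOP = 40.0  # m/s; stop the travel-speed series past this value


def sweep(
    species: Sequence[SpeciesMorphology],
    wind_model: WindModel,
    env: Environment | None = None,
    wind_step: float = 0.5,
    wind_upper: float | None = None,
    N: int = 51,
    multistart: int = 8,
    seed: int = 0,
    maxiter: int = 500,
) -> pd.DataFrame:
    """Minimum required wind and speed-vs-wind series for a set of species.

    For each species the minimum sustaining wind parameter Wmin is found
    first; travel- and upwind-speed maxima are then solved on a wind grid
    from the species' own Wmin up to the largest Wmin across the set + 2 m/s
    (or ``wind_upper``), warm-starting each solve from the previous wind.
    The travel-speed series stops after the first wind where it exceeds
    40 m/s.  Infeasible solves are recorded and the sweep continues.
    """
    env = env or Environment()
    rows = []
    wmin_solutions: dict[str, DynSoarSolution] = {}
    for morph in species:
        prob = DynSoarProblem(
            morph=morph, wind=wind_model, objective="min_wind", N=N,
            multistart=multistart, seed=seed, maxiter=maxiter, env=env,
        )
        sol = solve(prob)
        wmin_solutions[morph.name] = sol
        rows.append(
            {
                "species": morph.name,
                "wind_model": wind_model.label(),
                "wind_speed": sol.objective_value if sol.feasible else math.nan,
                "quantity": "Wmin",
                "value": sol.objective_value if sol.feasible else math.nan,
                "status": sol.status,
            }
        )
    wmins = [s.objective_value for s in wmin_solutions.values() if s.feasible]
    if wind_upper is None:
        if not wmins:
            return pd.DataFrame(rows)
        wind_upper = max(wmins) + 2.0

    for morph in species:
        base = wmin_solutions[morph.name]
        if not base.feasible:
            continue
        grid = np.arange(base.objective_value, wind_upper + 1e-9, wind_step)
        warm = {"max_travel_speed": base, "max_upwind_speed": base}
        travel_stopped = False
        for w in grid:
            for objective in ("max_travel_speed", "max_upwind_speed"):
                if objective == "max_travel_speed" and travel_stopped:
                    continue
                prob = DynSoarProblem(
                    morph=morph, wind=wind_model, objective=objective, N=N,
                    fixed_wind_speed=float(w), multistart=multistart, seed=seed,
                    maxiter=maxiter, env=env,
                )
                sol = solve(prob, warm_start=warm[objective])
                if sol.feasible:
                    warm[objective] = sol
                rows.append(
                    {
                        "species": morph.name,
                        "wind_model": wind_model.label(),
                        "wind_speed": float(w),
                        "quantity": objective,
                        "value": sol.objective_value if sol.feasible else math.nan,
                        "status": sol.status,
                    }
                )
                if (
                    objective == "max_travel_speed"
                    and sol.feasible
                    and sol.objective_value > TRAVEL_SPEED_STOP
                ):
                    travel_stopped = True
    return pd.DataFrame(rows)
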