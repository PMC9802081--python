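"""Thermal-soaring performance: glide polars and circling envelopes.

In a straight equilibrium glide at airspeed V the sinking speed is

    Vsink(V) = (rho/2) (Sw/(m g)) (beta*CDpro(CL) + 0.01) V^3
             + (m g/Sw) (2 k / (rho Ra beta^2 pi)) / V,

with the equilibrium lift coefficient CL = 2 m g / (rho beta Sw V^2), the
lift-dependent profile-drag parabola CDpro(CL), parasite drag written as
0.01 of the *unreduced* wing area, and the span-reduction factor

    beta(V) = (Bstop - V/Vs) / (Bstop - 1)     (linear rule, birds)
    beta(V) = 1                                 (fixed span, pterosaurs)

where Vs is the stall speed.  The glide ratio is sqrt(V^2 - Vsink^2)/Vsink.

Circling at bank angle phi with lift coefficient CL* maps the straight-glide
speed V(CL*) onto a circle of radius r = V(CL*)^2/(g sin phi) with sinking
speed Vsink(CL*)/(cos phi)^{3/2}.  Two circling envelopes are computed:

* optimal — for each radius, minimize the circling sink over (CL* <= CLmax,
  phi), the animal's true performance limit;
* parametric — hold CL* fixed (at the minimum-sink lift coefficient, or at
  CLmax) and sweep phi, the conservative "safety margin" envelope.

The ASK-14 motor glider bypasses the model polar: its measured polar
Vsink = 10/V + 5.2e-5 V^3 is used directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .morphology import DragPolarParams, Environment, SpeciesMorphology, stall_speed

__all__ = [
    "GlidePoint",
    "CirclingPoint",
    "StallError",
    "profile_drag_coefficient",
    "span_factor",
    "ask14_sink",
    "glide_sink",
    "min_sink",
    "max_glide_ratio",
    "limiting_radius",
    "airspeed_at_cl",
    "circling_envelope_optimal",
    "circling_envelope_parametric",
]

BETA_FLOOR = 0.05  # numerical floor for the span factor (never binds in valid polars)


class StallError(ValueError):
    """Requested airspeed below the stall speed."""


@dataclass(frozen=True)
class GlidePoint:
    V: float
    Vsink: float
    CL: float
    beta: float
    glide_ratio: float


@dataclass(frozen=True)
class CirclingPoint:
    r: float
    Vsink_circle: float
    phi: float
    CLstar: float
    V: float

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.Vsink_circle)


def profile_drag_coefficient(CL, params: DragPolarParams):
    """Lift-dependent profile drag CDpro_min + kpro (CL - CL_Dpro_min)^2."""
    if np.any(np.asarray(CL) < 0):
        raise ValueError("CL must be nonnegative")
    return params.profile_drag(CL)


def span_factor(V: float, Vs: float, span_rule: str, Bstop: float) -> float:
    """Fraction of wingspan (and wing area, and aspect ratio) retained at
    airspeed V.  Fixed-span wings return 1; the linear rule shrinks the wing
    from 1 at the stall speed down toward zero at V = Bstop*Vs."""
    if V <= 0 or Vs <= 0:
        raise ValueError("speeds must be positive")
    if span_rule == "fixed":
        return 1.0
    if span_rule != "linear_reduction":
        raise ValueError(f"unknown span rule {span_rule!r}")
    beta = (Bstop - V / Vs) / (Bstop - 1.0)
    if beta <= 0:
        raise ValueError(
            f"span factor nonpositive at V = {V:.3g} m/s (>= Bstop*Vs = {Bstop * Vs:.3g})"
        )
    return min(1.0, max(beta, BETA_FLOOR))


def ask14_sink(V):
    """Measured ASK-14 glide polar, Vsink = 10/V + 5.2e-5 V^3 [m/s]."""
    V = np.asarray(V, dtype=float)
    return 10.0 / V + 5.2e-5 * V**3


def _is_glider(morph: SpeciesMorphology) -> bool:
    return morph.group == "glider"


def glide_sink(V: float, morph: SpeciesMorphology, env: Environment | None = None) -> GlidePoint:
    """Straight-glide point at airspeed V (requires V >= stall speed)."""
    env = env or Environment()
    Vs = stall_speed(morph, env)
    if V < Vs * (1.0 - 1e-9):
        raise StallError(f"V = {V:.3g} m/s below stall speed {Vs:.3g} m/s")
    mg = morph.m * env.g
    if _is_glider(morph):
        vsink = float(ask14_sink(V))
        CL = 2.0 * mg / (env.rho * morph.Sw * V**2)
        beta = 1.0
    else:
        beta = span_factor(V, Vs, morph.span_rule, morph.Bstop)
        CL = 2.0 * mg / (env.rho * beta * morph.Sw * V**2)
        cdpro = profile_drag_coefficient(CL, morph.drag)
        drag = morph.drag
        vsink = (
            0.5 * env.rho * (morph.Sw / mg) * (beta * cdpro + drag.parasite_factor) * V**3
            + (mg / morph.Sw) * (2.0 * drag.k / (env.rho * morph.Ra * beta**2 * math.pi)) / V
        )
    ratio = math.sqrt(max(V**2 - vsink**2, 0.0)) / vsink
    return GlidePoint(V=V, Vsink=vsink, CL=CL, beta=beta, glide_ratio=ratio)


def _admissible_speed_range(
    morph: SpeciesMorphology, env: Environment, v_upper: float | None = None
) -> tuple[float, float]:
    Vs = stall_speed(morph, env)
    if _is_glider(morph):
        hi = 60.0
    elif morph.span_rule == "linear_reduction":
        # stay above the span-factor floor
        hi = Vs * (morph.Bstop - BETA_FLOOR * (morph.Bstop - 1.0)) * 0.999
    else:
        hi = 4.0 * Vs
    if v_upper is not None:
        hi = min(hi, v_upper)
    return Vs, hi


def min_sink(
    morph: SpeciesMorphology, env: Environment | None = None, v_upper: float | None = None
) -> GlidePoint:
    """Glide point of minimum sinking speed over the admissible speed range."""
    env = env or Environment()
    lo, hi = _admissible_speed_range(morph, env, v_upper)
    res = minimize_scalar(
        lambda v: glide_sink(v, morph, env).Vsink,
        bounds=(lo * (1.0 + 1e-9), hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [float(res.x), lo, hi]
    best = min(candidates, key=lambda v: glide_sink(v, morph, env).Vsink)
    return glide_sink(best, morph, env)


def max_glide_ratio(
    morph: SpeciesMorphology, env: Environment | None = None, v_upper: float | None = None
) -> tuple[float, float, float]:
    """Maximum of sqrt(V^2 - Vsink^2)/Vsink over admissible airspeeds.

    Returns (ratio, V at the ratio, Vsink at the ratio).  The polar is smooth
    and effectively unimodal in glide ratio; a bounded scalar search is used
    and the bracket endpoints are checked.
    """
    env = env or Environment()
    lo, hi = _admissible_speed_range(morph, env, v_upper)
    res = minimize_scalar(
        lambda v: -glide_sink(v, morph, env).glide_ratio,
        bounds=(lo * (1.0 + 1e-9), hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [float(res.x), lo * (1.0 + 1e-9), hi]
    best = max(candidates, key=lambda v: glide_sink(v, morph, env).glide_ratio)
    pt = glide_sink(best, morph, env)
    return pt.glide_ratio, pt.V, pt.Vsink


def limiting_radius(morph: SpeciesMorphology, env: Environment | None = None) -> float:
    """Smallest achievable circle radius, V(CLmax)^2/g = Vs^2/g."""
    env = env or Environment()
    return stall_speed(morph, env) ** 2 / env.g


def airspeed_at_cl(
    CLstar: float, morph: SpeciesMorphology, env: Environment | None = None
) -> float:
    """Straight-glide airspeed at lift coefficient CL*, solving the
    equilibrium V^2 beta(V) = 2 m g / (rho Sw CL*) self-consistently.

    For fixed-span wings this is the closed form sqrt(2mg/(rho Sw CL*)); for
    the linear span rule the root is bracketed on [Vs, Bstop*Vs)."""
    env = env or Environment()
    if CLstar <= 0:
        raise ValueError("CL* must be positive")
    if CLstar > morph.CLmax * (1.0 + 1e-9):
        raise ValueError(f"CL* = {CLstar:.3g} exceeds CLmax = {morph.CLmax:.3g}")
    mg = morph.m * env.g
    target = 2.0 * mg / (env.rho * morph.Sw * CLstar)
    if _is_glider(morph) or morph.span_rule == "fixed":
        return math.sqrt(target)
    Vs = stall_speed(morph, env)

    def f(v):
        return v**2 * span_factor(v, Vs, morph.span_rule, morph.Bstop) - target

    # V^2 beta(V) rises from Vs^2 to a peak at V = (2/3) Bstop Vs and falls
    # beyond it; bracket the physical (slow) branch only.
    lo = Vs * (1.0 - 1e-9)
    hi = Vs * (2.0 / 3.0) * morph.Bstop
    if f(lo) > 0:
        return Vs  # CL* = CLmax: the stall point itself
    if f(hi) < 0:
        raise ValueError("CL* below the minimum reachable under the span rule")
    return brentq(f, lo, hi, xtol=1e-10)


def _circle_point(
    CLstar: float, phi: float, morph: SpeciesMorphology, env: Environment
) -> CirclingPoint:
    V = airspeed_at_cl(CLstar, morph, env)
    vsink = glide_sink(V, morph, env).Vsink
    r = V**2 / (env.g * math.sin(phi))
    return CirclingPoint(
        r=r, Vsink_circle=vsink / math.cos(phi) ** 1.5, phi=phi, CLstar=CLstar, V=V
    )


def circling_envelope_optimal(
    r_grid,
    morph: SpeciesMorphology,
    env: Environment | None = None,
    phi_max: float = math.radians(89.9),
) -> list[CirclingPoint]:
    """Performance-limit circling envelope: for each radius r, minimize the
    circling sink Vsink(CL*)/(cos phi)^{3/2} over CL* <= CLmax and phi,
    subject to r = V(CL*)^2 / (g sin phi).

    Radii below the limiting radius get an infeasible marker (NaN sink).
    """
    env = env or Environment()
    r_lim = limiting_radius(morph, env)
    Vs = stall_speed(morph, env)
    out: list[CirclingPoint] = []
    for r in np.asarray(r_grid, dtype=float):
        if r < r_lim / math.sin(phi_max) * (1.0 - 1e-12):
            out.append(CirclingPoint(r=float(r), Vsink_circle=math.nan, phi=math.nan,
                                     CLstar=math.nan, V=math.nan))
            continue

        def sink_at(cl, r=float(r)):
            try:
                V = airspeed_at_cl(cl, morph, env)
            except ValueError:  # CL below the span rule's reachable range
                return math.inf
            s = V**2 / (env.g * r)
            if s > math.sin(phi_max):
                return math.inf
            phi = math.asin(s)
            vs = glide_sink(V, morph, env).Vsink
            return vs / math.cos(phi) ** 1.5

        # Feasible CL* range: V(CL*)^2 <= g r sin(phi_max), with V(CL*)
        # restricted to the invertible (slow) branch of the span rule.
        cl_hi = morph.CLmax
        v_cap = math.sqrt(env.g * float(r) * math.sin(phi_max))
        if _is_glider(morph) or morph.span_rule == "fixed":
            _, v_adm_hi = _admissible_speed_range(morph, env)
            v_eff = min(v_cap, v_adm_hi)
            beta_cap = 1.0
        else:
            v_eff = min(v_cap, (2.0 / 3.0) * morph.Bstop * Vs)
            beta_cap = span_factor(v_eff, Vs, morph.span_rule, morph.Bstop)
        mg = morph.m * env.g
        cl_lo = max(2.0 * mg / (env.rho * beta_cap * morph.Sw * v_eff**2) * (1 + 1e-9), 0.05)
        cl_lo = min(cl_lo, cl_hi)
        # coarse scan then local polish: the objective can be steep and
        # boundary-dominated at small radii
        grid = np.linspace(cl_lo, cl_hi, 33)
        vals = [sink_at(float(c)) for c in grid]
        k = int(np.argmin(vals))
        lo_b = grid[max(k - 1, 0)]
        hi_b = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            sink_at, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-8}
        )
        best_cl = min([float(res.x), float(grid[k]), cl_lo, cl_hi], key=sink_at)
        V = airspeed_at_cl(best_cl, morph, env)
        phi = math.asin(min(V**2 / (env.g * float(r)), 1.0))
        vs = glide_sink(V, morph, env).Vsink
        out.append(
            CirclingPoint(
                r=float(r),
                Vsink_circle=vs / math.cos(phi) ** 1.5,
                phi=phi,
                CLstar=best_cl,
                V=V,
            )
        )
    return out


def circling_envelope_parametric(
    phi_grid,
    morph: SpeciesMorphology,
    env: Environment | None = None,
    CLstar: float | str = "min_sink",
) -> list[CirclingPoint]:
    """Fixed-lift-coefficient circling envelope, swept parametrically in phi.

    ``CLstar`` may be a number, "min_sink" (the lift coefficient minimizing
    straight-glide sink, the conventional choice), or "max" (CLmax, the
    performance-limit variant used for the headline envelope tables).
    """
    env = env or Environment()
    if CLstar == "min_sink":
        pt = min_sink(morph, env)
        cl = pt.CL
    elif CLstar == "max":
        cl = morph.CLmax
    else:
        cl = float(CLstar)
    if cl > morph.CLmax * (1.0 + 1e-9):
        raise ValueError(f"CL* = {cl:.3g} exceeds CLmax = {morph.CLmax:.3g}")
    return [_circle_point(cl, float(phi), morph, env) for phi in np.asarray(phi_grid, float)]
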