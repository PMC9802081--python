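"""Synthetic morphologies and analytic trajectory fixtures.

The generator draws plausible flyer morphologies spanning the study's
mass / wing-loading / aspect-ratio ranges (mass sampled log-uniformly to
mirror the orders-of-magnitude spread between a petrel and a giant
pterosaur), and constructs exact still-air solutions of the equations of
motion — the equilibrium straight glide and the steady helical descent —
for use as zero-residual oracles in the collocation and EOM tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import Environment, SpeciesMorphology
from .thermal import profile_drag_coefficient

__all__ = ["SynthConfig", "gen_morphologies", "gen_fixture_trajectories",
           "FixtureTrajectory", "glide_equilibrium", "helix_solution"]

DEFAULT_SEED = 20220310


@dataclass(frozen=True)
class SynthConfig:
    seed: int = DEFAULT_SEED
    n_species: int = 20
    mass_range: tuple[float, float] = (1.0, 300.0)  # kg
    wing_loading_range: tuple[float, float] = (30.0, 250.0)  # N/m^2
    aspect_ratio_range: tuple[float, float] = (5.0, 18.0)
    pterosaur_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("mass_range", "wing_loading_range", "aspect_ratio_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if not 0.0 <= self.pterosaur_fraction <= 1.0:
            raise ValueError("pterosaur_fraction must lie in [0, 1]")


def gen_morphologies(config: SynthConfig | None = None,
                     env: Environment | None = None) -> list[SpeciesMorphology]:
    """Deterministic sample of synthetic morphologies.

    Mass is log-uniform; wing loading and aspect ratio are uniform.  Wing
    area follows from the loading (Sw = m g / loading) and wingspan from the
    aspect ratio (b = sqrt(Ra Sw)).  Group (and with it the drag set, CLmax,
    and span rule) is assigned by a biased coin.
    """
    config = config or SynthConfig()
    env = env or Environment()
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_species):
        m = math.exp(rng.uniform(*map(math.log, config.mass_range)))
        loading = rng.uniform(*config.wing_loading_range)
        ra = rng.uniform(*config.aspect_ratio_range)
        Sw = m * env.g / loading
        b = math.sqrt(ra * Sw)
        group = "pterosaur" if rng.random() < config.pterosaur_fraction else "bird"
        out.append(
            SpeciesMorphology(
                name=f"synth_{i:03d}", group=group, m=m, b=b, Sw=Sw,
                category="extinct" if group == "pterosaur" else "thermal_soarer",
            )
        )
    return out


@dataclass(frozen=True)
class FixtureTrajectory:
    """Exact still-air solution sampled on N nodes."""

    kind: str  # "glide" | "helix"
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    V: np.ndarray
    phi: np.ndarray
    CL: float
    tau: float
    # analytic invariants of the helix (NaN for the glide)
    radius: float = math.nan
    sink_rate: float = math.nan

    def nodes(self) -> dict:
        return {k: getattr(self, k) for k in ("x", "y", "z", "gamma", "psi", "V", "phi")}


def _total_drag_coefficient(CL: float, morph: SpeciesMorphology) -> float:
    d = morph.drag
    return (
        profile_drag_coefficient(CL, d)
        + d.parasite_factor
        + d.k * CL**2 / (math.pi * morph.Ra)
    )


def glide_equilibrium(CL: float, morph: SpeciesMorphology,
                      env: Environment | None = None) -> tuple[float, float]:
    """Exact equilibrium (V, gamma) of a wings-level still-air glide at CL.

    Solves L = m g cos(gamma), D = m g sin(gamma) with the full (not
    small-angle) force balance: tan(gamma) = CD/CL and
    V^2 = 2 m g cos(gamma) / (rho CL Sw)."""
    env = env or Environment()
    CD = _total_drag_coefficient(CL, morph)
    gamma = math.atan2(CD, CL)
    V = math.sqrt(2.0 * morph.m * env.g * math.cos(gamma) / (env.rho * CL * morph.Sw))
    return V, gamma


def helix_solution(CL: float, phi: float, morph: SpeciesMorphology,
                   env: Environment | None = None) -> dict:
    """Exact steady helical descent (constant V, gamma, phi; uniform turn).

    From the banked force balance L cos(phi) = m g cos(gamma),
    D = m g sin(gamma): tan(gamma) = CD/(CL cos(phi)),
    V^2 = 2 m g cos(gamma)/(rho CL Sw cos(phi)), turn rate
    dpsi/dt = L sin(phi)/(m V cos(gamma))."""
    env = env or Environment()
    CD = _total_drag_coefficient(CL, morph)
    cp = math.cos(phi)
    gamma = math.atan2(CD, CL * cp)
    V = math.sqrt(2.0 * morph.m * env.g * math.cos(gamma) / (env.rho * CL * morph.Sw * cp))
    L = 0.5 * env.rho * CL * morph.Sw * V**2
    psidot = L * math.sin(phi) / (morph.m * V * math.cos(gamma))
    radius = V * math.cos(gamma) / psidot
    return {"V": V, "gamma": gamma, "psidot": psidot, "radius": radius,
            "sink_rate": V * math.sin(gamma)}


def gen_fixture_trajectories(morph: SpeciesMorphology,
                             env: Environment | None = None,
                             N: int = 51,
                             z0: float = 50.0,
                             banks: tuple[float, ...] = (15.0, 30.0, 45.0)
                             ) -> list[FixtureTrajectory]:
    """Analytic still-air fixtures: one equilibrium straight glide and
    helical descents at the requested bank angles (degrees).

    The glide runs for a nominal 6 s; each helix covers one full turn, so its
    period matches the collocation cycle period."""
    env = env or Environment()
    CL = min(0.8 * morph.CLmax, 1.0)
    out: list[FixtureTrajectory] = []

    V, gamma = glide_equilibrium(CL, morph, env)
    tau = 6.0
    t = np.linspace(0.0, tau, N)
    out.append(
        FixtureTrajectory(
            kind="glide",
            t=t,
            x=V * math.cos(gamma) * t,
            y=np.zeros(N),
            z=z0 - V * math.sin(gamma) * t,
            gamma=np.full(N, gamma),
            psi=np.zeros(N),
            V=np.full(N, V),
            phi=np.zeros(N),
            CL=CL,
            tau=tau,
        )
    )

    for phi_deg in banks:
        phi = math.radians(phi_deg)
        h = helix_solution(CL, phi, morph, env)
        # helix load factor is cos(gamma)/cos(phi); keep fixtures within the cap
        if math.cos(h["gamma"]) / math.cos(phi) > 3.0:
            raise ValueError(f"bank {phi_deg} deg exceeds the load-factor cap")
        tau = 2.0 * math.pi / h["psidot"]
        t = np.linspace(0.0, tau, N)
        psi = h["psidot"] * t
        vh = h["V"] * math.cos(h["gamma"])
        out.append(
            FixtureTrajectory(
                kind=f"helix_{phi_deg:g}",
                t=t,
                x=vh / h["psidot"] * np.sin(psi),
                y=vh / h["psidot"] * (1.0 - np.cos(psi)),
                z=z0 - h["sink_rate"] * t,
                gamma=np.full(N, h["gamma"]),
                psi=psi,
                V=np.full(N, h["V"]),
                phi=np.full(N, phi),
                CL=CL,
                tau=tau,
                radius=h["radius"],
                sink_rate=h["sink_rate"],
            )
        )
    return out
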