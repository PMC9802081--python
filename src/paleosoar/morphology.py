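"""Species morphologies and derived flight quantities.

Holds the built-in registry of the study animals (four extinct giants, nine
extant reference birds, one motor glider), the group-specific drag-polar
coefficient sets, and the closed-form derived quantities (wing loading,
aspect ratio, stall speed).  The 24 alternative *Pelagornis sandersi*
reconstructions are expanded from the published mass / wingspan / aspect-ratio
estimate grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "DragPolarParams",
    "Environment",
    "SpeciesMorphology",
    "BIRD_DRAG",
    "PTEROSAUR_FAIRED_DRAG",
    "PTEROSAUR_UNFAIRED_DRAG",
    "DRAG_SETS",
    "wing_loading",
    "aspect_ratio",
    "stall_speed",
    "expand_pelagornis_configs",
    "registry",
    "load_registry_csv",
    "write_registry_csv",
]

G_STANDARD = 9.81  # m/s^2
RHO_SEA_LEVEL = 1.23  # kg/m^3, International Standard Atmosphere at 15 degC
RHO_HIGH_OXYGEN = 1.48  # kg/m^3, 1.2x present-day density (sensitivity case)


@dataclass(frozen=True)
class Environment:
    """Ambient air and gravity.

    rho defaults to the sea-level ISA density; the high-oxygen sensitivity
    scenario uses 1.48 kg/m^3.  g is standard gravity.
    """

    rho: float = RHO_SEA_LEVEL
    g: float = G_STANDARD

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.g <= 0:
            raise ValueError("air density and gravity must be positive")


@dataclass(frozen=True)
class DragPolarParams:
    """Coefficients of the lift-dependent profile-drag parabola plus the
    induced- and parasite-drag constants.

    CDpro(CL) = CDpro_min + kpro * (CL - CL_Dpro_min)^2.  The parasite drag
    area is expressed as a fraction of wing area (CDpar * SB = 0.01 * SW),
    because neither the body drag coefficient nor the frontal area is known
    separately for these animals.
    """

    CDpro_min: float
    kpro: float
    CL_Dpro_min: float
    k: float = 1.1
    parasite_factor: float = 0.01

    def __post_init__(self) -> None:
        for name in ("CDpro_min", "kpro", "CL_Dpro_min", "k", "parasite_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def profile_drag(self, CL):
        return self.CDpro_min + self.kpro * (CL - self.CL_Dpro_min) ** 2


# Bird set: wind-tunnel glide of a jackdaw.  Pterosaur sets: wind-tunnel
# measurements on reconstructed ~6 m membrane wings, faired and unfaired.
BIRD_DRAG = DragPolarParams(0.019, 0.030, 0.77)
PTEROSAUR_FAIRED_DRAG = DragPolarParams(0.050, 0.11, 1.0)
PTEROSAUR_UNFAIRED_DRAG = DragPolarParams(0.077, 0.065, 0.89)

DRAG_SETS = {
    "bird": BIRD_DRAG,
    "pterosaur_faired": PTEROSAUR_FAIRED_DRAG,
    "pterosaur_unfaired": PTEROSAUR_UNFAIRED_DRAG,
}

_GROUPS = ("bird", "pterosaur", "glider")
_SPAN_RULES = ("linear_reduction", "fixed")
_CATEGORIES = ("extinct", "dynamic_soarer", "thermal_soarer", "non_soarer", "glider")


@dataclass(frozen=True)
class SpeciesMorphology:
    """One morphological reconstruction: mass, wingspan, wing area, and the
    aerodynamic settings tied to its group.

    ``Ra`` stores the published aspect ratio when one was printed (rounded to
    3 significant figures); it must agree with b^2/Sw within 1%.  ``category``
    records the ecological grouping used to organize the comparison (extinct
    giant, dynamic soarer, thermal soarer, non-soarer, glider).
    """

    name: str
    group: str
    m: float
    b: float
    Sw: float
    Ra: float | None = None
    CLmax: float | None = None
    drag_set: str | None = None
    span_rule: str | None = None
    Bstop: float | None = None
    category: str = "extinct"

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.m <= 0 or self.b <= 0 or self.Sw <= 0:
            raise ValueError("mass, wingspan, and wing area must be positive")
        derived_ra = self.b**2 / self.Sw
        if self.Ra is None:
            object.__setattr__(self, "Ra", derived_ra)
        elif abs(self.Ra - derived_ra) / self.Ra > 0.01:
            raise ValueError(
                f"{self.name}: aspect ratio {self.Ra} inconsistent with "
                f"b^2/Sw = {derived_ra:.4g}"
            )
        # Group defaults: birds flex their wings at speed (linear span
        # reduction, Bstop = 5, CLmax 1.8); pterosaur membrane wings are kept
        # at fixed span, with CLmax 2.0 and the faired coefficient set.
        if self.CLmax is None:
            object.__setattr__(
                self, "CLmax", {"bird": 1.8, "pterosaur": 2.0, "glider": 1.3}[self.group]
            )
        if self.CLmax <= 0:
            raise ValueError("CLmax must be positive")
        if self.drag_set is None:
            default = {"bird": "bird", "pterosaur": "pterosaur_faired", "glider": "bird"}
            object.__setattr__(self, "drag_set", default[self.group])
        if self.drag_set not in DRAG_SETS:
            raise ValueError(f"unknown drag set {self.drag_set!r}")
        if self.span_rule is None:
            rule = "linear_reduction" if self.group == "bird" else "fixed"
            object.__setattr__(self, "span_rule", rule)
        if self.span_rule not in _SPAN_RULES:
            raise ValueError(f"unknown span rule {self.span_rule!r}")
        if self.Bstop is None:
            object.__setattr__(self, "Bstop", 5.0 if self.group == "bird" else 6.0)
        if self.Bstop <= 1:
            raise ValueError("Bstop must exceed 1")

    @property
    def drag(self) -> DragPolarParams:
        return DRAG_SETS[self.drag_set]

    def wing_loading(self, env: Environment | None = None) -> float:
        return wing_loading(self.m, self.Sw, env)

    def stall_speed(self, env: Environment | None = None) -> float:
        return stall_speed(self, env)


def wing_loading(m: float, Sw: float, env: Environment | None = None) -> float:
    """Weight per unit wing area, m*g/Sw [N/m^2]."""
    if m <= 0 or Sw <= 0:
        raise ValueError("mass and wing area must be positive")
    g = (env or Environment()).g
    return m * g / Sw


def aspect_ratio(b: float, Sw: float) -> float:
    """Wingspan squared over wing area, b^2/Sw."""
    if b <= 0 or Sw <= 0:
        raise ValueError("wingspan and wing area must be positive")
    return b**2 / Sw


def stall_speed(morph: SpeciesMorphology, env: Environment | None = None) -> float:
    """Minimum equilibrium airspeed sqrt(2 m g / (rho Sw CLmax)).

    Uses the unreduced wing area: at the stall the span-reduction factor is 1.
    """
    env = env or Environment()
    return math.sqrt(2.0 * morph.m * env.g / (env.rho * morph.Sw * morph.CLmax))


# --- built-in registry -----------------------------------------------------

PELAGORNIS_MASSES = (21.8, 40.1)  # kg
PELAGORNIS_SPANS = (6.06, 6.13, 6.40, 7.38)  # m
PELAGORNIS_ASPECT_RATIOS = (13.0, 14.0, 15.0)


def expand_pelagornis_configs() -> list[SpeciesMorphology]:
    """All 24 *P. sandersi* reconstructions: {2 masses} x {4 spans} x
    {3 aspect ratios}, wing area derived as b^2/Ra."""
    configs = []
    for m in PELAGORNIS_MASSES:
        for b in PELAGORNIS_SPANS:
            for ra in PELAGORNIS_ASPECT_RATIOS:
                configs.append(
                    SpeciesMorphology(
                        name=f"pelagornis_sandersi_m{m:g}_b{b:g}_ra{ra:g}",
                        group="bird",
                        m=m,
                        b=b,
                        Sw=b**2 / ra,
                        Ra=ra,
                        category="extinct",
                    )
                )
    return configs


def _builtin_entries() -> list[SpeciesMorphology]:
    E = SpeciesMorphology
    return [
        # extinct giants (P. sandersi is represented by its 24 configurations)
        E("argentavis_magnificens", "bird", 70.0, 7.00, 8.11, 6.04, category="extinct"),
        E("pteranodon_witton", "pterosaur", 36.7, 5.96, 1.99, 17.9, category="extinct"),
        E("pteranodon_henderson", "pterosaur", 18.6, 5.34, 2.26, 12.6, category="extinct"),
        E("quetzalcoatlus", "pterosaur", 259.0, 9.64, 11.4, 8.18, category="extinct"),
        # extant dynamic soarers
        E("wandering_albatross", "bird", 8.64, 3.05, 0.606, 15.4, category="dynamic_soarer"),
        E("black_browed_albatross", "bird", 3.55, 2.25, 0.376, 13.4, category="dynamic_soarer"),
        E("white_chinned_petrel", "bird", 1.37, 1.40, 0.169, 11.6, category="dynamic_soarer"),
        # extant thermal soarers
        E("magnificent_frigatebird", "bird", 1.52, 2.29, 0.408, 12.8, category="thermal_soarer"),
        E("california_condor", "bird", 9.50, 2.74, 1.32, 5.70, category="thermal_soarer"),
        E("brown_pelican", "bird", 2.65, 2.10, 0.450, 9.80, category="thermal_soarer"),
        E("black_vulture", "bird", 1.82, 1.38, 0.327, 5.82, category="thermal_soarer"),
        # white stork: the published wingspan (2.18 m) is inconsistent with the
        # published wing area, aspect ratio, and wing loading, which agree with
        # each other; the span is back-derived as sqrt(Ra*Sw) = 2.00 m.
        E("white_stork", "bird", 3.40, 2.002, 0.540, 7.42, category="thermal_soarer"),
        # heaviest extant volant bird that does not soar
        E("kori_bustard", "bird", 11.9, 2.47, 1.06, 5.76, category="non_soarer"),
        # motor glider reference (measured polar; CLmax 1.3 for its envelope)
        E("ask14", "glider", 340.0, 14.3, 12.6, 16.2, CLmax=1.3, category="glider"),
    ]


def registry(include_pelagornis: bool = False) -> dict[str, SpeciesMorphology]:
    """Built-in morphology registry keyed by name.

    With ``include_pelagornis`` the 24 *P. sandersi* configurations are added
    as individual entries.
    """
    entries = {e.name: e for e in _builtin_entries()}
    if include_pelagornis:
        for cfg in expand_pelagornis_configs():
            entries[cfg.name] = cfg
    return entries


_CSV_COLUMNS = [
    "name",
    "group",
    "mass_kg",
    "wingspan_m",
    "wing_area_m2",
    "aspect_ratio",
    "clmax",
    "drag_set",
    "span_rule",
    "bstop",
    "category",
]


def write_registry_csv(entries: Iterable[SpeciesMorphology], path) -> None:
    rows = [
        {
            "name": e.name,
            "group": e.group,
            "mass_kg": e.m,
            "wingspan_m": e.b,
            "wing_area_m2": e.Sw,
            "aspect_ratio": e.Ra,
            "clmax": e.CLmax,
            "drag_set": e.drag_set,
            "span_rule": e.span_rule,
            "bstop": e.Bstop,
            "category": e.category,
        }
        for e in entries
    ]
    # %.17g guarantees exact float round-trips through the CSV dialect
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def load_registry_csv(path) -> dict[str, SpeciesMorphology]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
    out: dict[str, SpeciesMorphology] = {}
    for row in df.itertuples(index=False):
        entry = SpeciesMorphology(
            name=row.name,
            group=row.group,
            m=float(row.mass_kg),
            b=float(row.wingspan_m),
            Sw=float(row.wing_area_m2),
            Ra=float(row.aspect_ratio),
            CLmax=float(row.clmax),
            drag_set=row.drag_set,
            span_rule=row.span_rule,
            Bstop=float(row.bstop),
            category=getattr(row, "category", "extinct"),
        )
        out[entry.name] = entry
    return out
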