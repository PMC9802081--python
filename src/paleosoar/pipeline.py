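"""Orchestration of the full soaring comparison.

``run_thermal`` computes, for every configuration in the comparison (the 24
*P. sandersi* reconstructions, the other three extinct giants, the nine
extant reference birds, and the ASK-14 motor glider), the glide polar, the
circling envelope, and a summary row (limiting radius, minimum straight-glide
sink, maximum glide ratio and the speed at which it occurs).

``run_dynamic`` solves the dynamic-soaring problems — minimum required wind
and cycle-averaged travel / upwind speed maxima — for a species set across a
grid of wind-shear conditions.

Both return pandas DataFrames and optionally write CSV files; the numbered
scripts under ``analysis/`` are thin drivers over these functions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamic, thermal
from .morphology import Environment, SpeciesMorphology, expand_pelagornis_configs, registry
from .wind import WindModel, standard_wind_grid

__all__ = ["RunConfig", "thermal_config_set", "dynamic_species_set",
           "run_thermal", "run_dynamic"]


@dataclass(frozen=True)
class RunConfig:
    """Options shared by the pipeline stages; defaults reproduce the study
    setup (sea-level density, 51 collocation nodes, bank cap 40 degrees for
    the headline envelope tables)."""

    rho: float = 1.23
    envelope_definition: str = "optimal"  # "optimal" | "parametric"
    envelope_clstar: str | float = "max"  # parametric variant's fixed CL*
    bank_cap_deg: float = 40.0
    n_envelope_radii: int = 40
    N: int = 51
    multistart: int = 8
    seed: int = 0
    maxiter: int = 500
    sweep_step: float = 0.5
    out_dir: str | None = None

    @property
    def env(self) -> Environment:
        return Environment(rho=self.rho)


def config_hash(config: RunConfig) -> str:
    """Deterministic short hash of the scientific run settings (provenance);
    the output path does not participate."""
    from dataclasses import replace

    return hashlib.sha256(repr(replace(config, out_dir=None)).encode()).hexdigest()[:12]


def _write_run_metadata(out_dir: Path, config: RunConfig, **extra) -> None:
    from . import __version__

    meta = {"package_version": __version__, "config_hash": config_hash(config),
            "config": repr(config)}
    meta.update(extra)
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def thermal_config_set() -> list[SpeciesMorphology]:
    """The 38 thermal-stage configurations: 24 P. sandersi + Argentavis +
    2 Pteranodon + Quetzalcoatlus + 9 extant birds + ASK-14."""
    reg = registry()
    extinct_named = [reg[n] for n in
                     ("argentavis_magnificens", "pteranodon_witton",
                      "pteranodon_henderson", "quetzalcoatlus")]
    extant = [e for e in reg.values()
              if e.category in ("dynamic_soarer", "thermal_soarer", "non_soarer")]
    glider = [reg["ask14"]]
    return expand_pelagornis_configs() + extinct_named + extant + glider


def dynamic_species_set(pelagornis: str = "all") -> list[SpeciesMorphology]:
    """Default dynamic-stage species: the three extant dynamic soarers plus
    the four extinct giants.  ``pelagornis`` selects which reconstructions
    participate: "all" (24), "light"/"heavy" (12 each), or a single name."""
    reg = registry(include_pelagornis=True)
    out = [reg[n] for n in
           ("white_chinned_petrel", "black_browed_albatross", "wandering_albatross")]
    pel = expand_pelagornis_configs()
    if pelagornis == "all":
        out += pel
    elif pelagornis == "light":
        out += [p for p in pel if p.m < 30.0]
    elif pelagornis == "heavy":
        out += [p for p in pel if p.m > 30.0]
    else:
        out += [reg[pelagornis]]
    out += [reg[n] for n in ("argentavis_magnificens", "pteranodon_witton",
                             "pteranodon_henderson", "quetzalcoatlus")]
    return out


def run_thermal(config: RunConfig | None = None,
                species: list[SpeciesMorphology] | None = None
                ) -> dict[str, pd.DataFrame]:
    """Thermal stage: polars, envelopes, and the summary table.

    Returns {"polars": ..., "envelopes": ..., "summary": ...}; writes CSVs
    when the config has an output directory.
    """
    config = config or RunConfig()
    env = config.env
    species = species if species is not None else thermal_config_set()
    polar_rows, env_rows, summary_rows = [], [], []
    phi_cap = math.radians(config.bank_cap_deg)
    for morph in species:
        vs = morph.stall_speed(env)
        lo, hi = thermal._admissible_speed_range(morph, env)
        for V in np.linspace(lo * (1 + 1e-9), hi, 60):
            pt = thermal.glide_sink(float(V), morph, env)
            polar_rows.append({"species": morph.name, "V": pt.V, "Vsink": pt.Vsink,
                               "CL": pt.CL, "beta": pt.beta})
        ratio, v_at, vsink_at = thermal.max_glide_ratio(morph, env)
        msink = thermal.min_sink(morph, env)
        r_lim = thermal.limiting_radius(morph, env)
        summary_rows.append(
            {
                "species": morph.name,
                "category": morph.category,
                "mass_kg": morph.m,
                "wing_loading": morph.wing_loading(env),
                "aspect_ratio": morph.Ra,
                "limiting_radius_m": r_lim,
                "min_sink_ms": msink.Vsink,
                "speed_at_min_sink_ms": msink.V,
                "max_glide_ratio": ratio,
                "speed_at_max_glide_ratio_ms": v_at,
                "sink_at_max_glide_ratio_ms": vsink_at,
            }
        )
        # envelope: radii from just above the bank-capped limiting radius out
        # to 10^4 m (log spaced)
        if config.envelope_definition == "optimal":
            r0 = 1.05 * r_lim / math.sin(phi_cap)
            radii = np.geomspace(r0, 1e4, config.n_envelope_radii)
            points = thermal.circling_envelope_optimal(radii, morph, env,
                                                       phi_max=phi_cap)
        else:
            phis = np.linspace(phi_cap, math.radians(1.0), config.n_envelope_radii)
            points = thermal.circling_envelope_parametric(
                phis, morph, env, CLstar=config.envelope_clstar)
        for p in points:
            env_rows.append({"species": morph.name, "r": p.r,
                             "Vsink_circle": p.Vsink_circle, "phi": p.phi,
                             "CLstar": p.CLstar})
    out = {
        "polars": pd.DataFrame(polar_rows),
        "envelopes": pd.DataFrame(env_rows),
        "summary": pd.DataFrame(summary_rows),
    }
    if config.out_dir:
        d = Path(config.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for key, df in out.items():
            df.to_csv(d / f"thermal_{key}.csv", index=False)
        _write_run_metadata(d, config, stage="thermal",
                            n_configurations=len(species))
    return out


def run_dynamic(config: RunConfig | None = None,
                species: list[SpeciesMorphology] | None = None,
                wind_models: list[WindModel] | None = None,
                objectives: tuple[str, ...] = ("min_wind",),
                reference_wind: float | None = None) -> pd.DataFrame:
    """Dynamic stage over a wind-condition grid.

    For every wind model: the minimum required wind per species and —
    when ``reference_wind`` is given — the travel / upwind speed maxima at
    that profile parameter.  Infeasible solves are recorded as NaN rows.
    """
    config = config or RunConfig()
    env = config.env
    species = species if species is not None else dynamic_species_set("light")
    wind_models = wind_models if wind_models is not None else standard_wind_grid()
    rows = []
    for wm in wind_models:
        for morph in species:
            warm = None
            for objective in objectives:
                kwargs = dict(
                    morph=morph, wind=wm, objective=objective, N=config.N,
                    multistart=config.multistart, seed=config.seed,
                    maxiter=config.maxiter, env=env,
                )
                if objective != "min_wind":
                    if reference_wind is None:
                        continue
                    kwargs["fixed_wind_speed"] = reference_wind
                sol = dynamic.solve(dynamic.DynSoarProblem(**kwargs), warm_start=warm)
                if sol.feasible:
                    warm = sol
                rows.append(
                    {
                        "species": morph.name,
                        "wind_model": wm.label(),
                        "objective": objective,
                        "wind_speed": (sol.wind_param if sol.feasible else math.nan),
                        "value": sol.objective_value,
                        "status": sol.status,
                        "CL": sol.CL,
                        "tau": sol.tau,
                        "energy_residual": sol.energy_residual,
                    }
                )
    df = pd.DataFrame(rows)
    if config.out_dir:
        d = Path(config.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        df.to_csv(d / "dynamic_results.csv", index=False)
        _write_run_metadata(d, config, stage="dynamic", n_solves=len(df))
    return df
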