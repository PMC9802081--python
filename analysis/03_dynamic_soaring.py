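#!/usr/bin/env python
"""Dynamic-soaring stage: minimum required winds and travel speeds.

For the three extant dynamic soarers and the four extinct giants, solves
the periodic trajectory-optimization problem under a configurable subset of
the seven wind-shear conditions (default: the logarithmic profile plus the
two hw = 3 m sigmoidal layers — pass --all-conditions for the full grid)
and, at a 10 m/s reference wind, the maximum cycle-averaged travel and
upwind speeds for the species that can sustain a cycle there.

Writes results/dynamic_wmin.csv and results/dynamic_speeds.csv.  An
infeasible minimum-wind row means the requirement exceeds the 40 m/s
wind-parameter bound.  Expect roughly half an hour on one CPU with the
default 3-condition scope.
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from paleosoar.dynamic import DynSoarProblem, solve
from paleosoar.morphology import registry
from paleosoar.wind import WindModel, standard_wind_grid

OUT = Path(__file__).resolve().parents[1] / "results"
SPECIES = [
    "white_chinned_petrel",
    "black_browed_albatross",
    "wandering_albatross",
    "pelagornis_sandersi_m21.8_b6.4_ra14",
    "argentavis_magnificens",
    "pteranodon_witton",
    "quetzalcoatlus",
]
REFERENCE_WIND = 10.0


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--all-conditions", action="store_true")
    ap.add_argument("--multistart", type=int, default=4)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    if args.all_conditions:
        conditions = standard_wind_grid()
    else:
        conditions = [
            WindModel("logarithmic", W10=10.0),
            WindModel("sigmoidal", Wmax=10.0, hw=3.0, delta=3 / 6),
            WindModel("sigmoidal", Wmax=10.0, hw=3.0, delta=7 / 6),
        ]
    reg = registry(include_pelagornis=True)
    wmin_rows, speed_rows = [], []
    for wm in conditions:
        for name in SPECIES:
            t0 = time.time()
            prob = DynSoarProblem(morph=reg[name], wind=wm, objective="min_wind",
                                  multistart=args.multistart, seed=args.seed)
            sol = solve(prob)
            wmin_rows.append({
                "species": name, "wind_model": wm.label(),
                "wmin_ms": sol.objective_value if sol.feasible else float("nan"),
                "status": sol.status, "tau_s": sol.tau, "CL": sol.CL,
                "energy_residual": sol.energy_residual,
            })
            print(f"{wm.label():24s} {name:38s} Wmin "
                  f"{sol.objective_value:6.2f}" if sol.feasible else
                  f"{wm.label():24s} {name:38s} Wmin  > 40 (no cycle)",
                  f"[{time.time() - t0:5.1f} s]")
            if sol.feasible and sol.objective_value < REFERENCE_WIND:
                for objective in ("max_travel_speed", "max_upwind_speed"):
                    sp = solve(DynSoarProblem(
                        morph=reg[name], wind=wm, objective=objective,
                        fixed_wind_speed=REFERENCE_WIND,
                        multistart=2, seed=args.seed), warm_start=sol)
                    speed_rows.append({
                        "species": name, "wind_model": wm.label(),
                        "wind_ms": REFERENCE_WIND, "objective": objective,
                        "speed_ms": sp.objective_value if sp.feasible else float("nan"),
                        "speed_kmh": sp.objective_value * 3.6 if sp.feasible else float("nan"),
                        "status": sp.status,
                    })
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(wmin_rows).to_csv(OUT / "dynamic_wmin.csv", index=False)
    pd.DataFrame(speed_rows).to_csv(OUT / "dynamic_speeds.csv", index=False)
    sp = pd.DataFrame(speed_rows)
    if len(sp):
        best = sp[sp.objective == "max_travel_speed"].speed_kmh.max()
        print(f"\nbest travel speed at {REFERENCE_WIND:.0f} m/s wind: {best:.1f} km/h")
    print(f"wrote dynamic_wmin.csv, dynamic_speeds.csv under {OUT}")


if __name__ == "__main__":
    main()
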