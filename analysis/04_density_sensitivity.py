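#!/usr/bin/env python
"""Air-density sensitivity: rerun key comparisons at 1.48 kg/m^3.

A 20% denser atmosphere (the upper bound of plausible paleo-atmospheres)
lowers every speed scale by sqrt(1.23/1.48) ~ 0.91 but leaves the
between-species comparisons intact: the giants still need more wind for
dynamic soaring than the wandering albatross, and Quetzalcoatlus still
sinks faster than any extant soarer while circling.  Writes
results/density_sensitivity.csv.
"""

from pathlib import Path

import pandas as pd

from paleosoar.dynamic import DynSoarProblem, solve
from paleosoar.morphology import Environment, registry
from paleosoar.thermal import min_sink
from paleosoar.wind import WindModel

OUT = Path(__file__).resolve().parents[1] / "results"
SIG = WindModel("sigmoidal", Wmax=10.0, hw=3.0, delta=7 / 6)
DYNAMIC_SPECIES = ["wandering_albatross", "pelagornis_sandersi_m40.1_b6.4_ra14",
                   "pteranodon_witton"]
THERMAL_SPECIES = ["wandering_albatross", "california_condor", "quetzalcoatlus"]


def main() -> None:
    reg = registry(include_pelagornis=True)
    rows = []
    for rho in (1.23, 1.48):
        env = Environment(rho=rho)
        for name in THERMAL_SPECIES:
            rows.append({"rho": rho, "species": name, "quantity": "min_sink_ms",
                         "value": min_sink(reg[name], env).Vsink})
        for name in DYNAMIC_SPECIES:
            sol = solve(DynSoarProblem(morph=reg[name], wind=SIG,
                                       objective="min_wind", multistart=4,
                                       seed=0, env=env))
            rows.append({"rho": rho, "species": name, "quantity": "wmin_ms",
                         "value": sol.objective_value if sol.feasible else float("nan")})
            print(f"rho={rho:.2f} {name:38s} Wmin "
                  + (f"{sol.objective_value:6.2f}" if sol.feasible else " > 40"))
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "density_sensitivity.csv", index=False)
    for rho in (1.23, 1.48):
        sub = df[(df.rho == rho) & (df.quantity == "wmin_ms")].set_index("species")
        alb = sub.loc["wandering_albatross", "value"]
        others = sub.drop("wandering_albatross")["value"]
        ok = bool((others.fillna(float("inf")) > alb).all())
        print(f"rho={rho:.2f}: albatross needs the least wind -> {ok}")
    print(f"wrote {OUT / 'density_sensitivity.csv'}")


if __name__ == "__main__":
    main()
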