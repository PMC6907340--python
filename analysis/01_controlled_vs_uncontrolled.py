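"""Genetic response with and without controlled mating.

Runs a matched pair of 20-year breeding schemes at reduced replication --
controlled mating on isolated stations vs. free mating against an equally
large passive population -- and reports the genetic gain from year 5 to 20
and the percentage reduction caused by giving up mating control.

Desk-scale defaults (N_b = 500, 5 replicates) finish in a few minutes;
`--full` uses the study sizes (N_b = 1000, 10 replicates).
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from apiselect import experiment as xp  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=5)
    ap.add_argument("--full", action="store_true")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    n_b = 1000 if args.full else 500
    reps = 10 if args.full else args.replicates
    controlled = xp.Setting(N_b=n_b, N_p=0, N_s=10, q=0.0, sigma_Amd=-0.75)
    free = xp.Setting(N_b=n_b, N_p=n_b, N_s=0, q=0.0, sigma_Amd=-0.75)

    rows = []
    for name, setting in (("controlled", controlled), ("uncontrolled", free)):
        for rep in range(reps):
            t = xp.run_replicate(setting, xp.replicate_seed(args.seed, rep))
            rows.append(
                dict(
                    scheme=name,
                    replicate=rep,
                    gain_5_20=xp.genetic_gain(t),
                    gain_year5=xp.accumulated_gain(t, 5),
                    mean_F_final=float(t.bq_mean_F[-1]),
                )
            )
    df = pd.DataFrame(rows)
    summary = df.groupby("scheme")[["gain_5_20", "gain_year5"]].agg(["mean", "sem"])
    g_c = df[df.scheme == "controlled"].gain_5_20.mean()
    g_u = df[df.scheme == "uncontrolled"].gain_5_20.mean()
    reduction = 100 * (1 - g_u / g_c)

    print(summary.round(3).to_string())
    print(
        f"\nGiving up mating control reduces the 15-year gain by {reduction:.0f}% "
        f"({g_c:.2f} -> {g_u:.2f} trait units) at N_b={n_b}, N_p={n_b}."
    )
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "01_controlled_vs_uncontrolled.csv", index=False)


if __name__ == "__main__":
    main()
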