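#!/usr/bin/env python
"""Generate one synthetic year of hourly PM2.5 + meteorology per city.

The study's raw monitoring feeds were never released, so seven
synthetic cities stand in for them, drawn from the seasonal linear
generative model with known coefficients (see pmhia.synthetic).  Hourly
CSVs land under scratch/simdata/<city>/ (large, regenerable); the
ground-truth records are summarised in results/simulation_truth.json.

Later scripts regenerate the same cities deterministically from the
seeds recorded here rather than re-reading the CSVs.
"""

import json
from pathlib import Path

from pmhia.reference import CITIES
from pmhia.synthetic import SimConfig, simulate_hourly, write_sim_dir

BASE_SEED = 2019
ROOT = Path(__file__).resolve().parents[1]


def city_config(city: str) -> SimConfig:
    return SimConfig(seed=BASE_SEED + CITIES.index(city))


def main() -> None:
    truth_summary = {}
    for city in CITIES:
        result = simulate_hourly(city_config(city))
        outdir = ROOT / "scratch" / "simdata" / city
        write_sim_dir(result, outdir)
        truth_summary[city] = result.truth
        print(
            f"{city:8s} seed={result.truth['seed']} "
            f"{len(result.pm25)} PM2.5 hours, "
            f"{result.truth['n_nonpositive']} sentinel value(s), "
            f"{result.truth['n_missing']['pm25']} missing hour(s)"
        )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "simulation_truth.json", "w") as fh:
        json.dump(truth_summary, fh, indent=2)
    print(f"\ntruth records -> {results / 'simulation_truth.json'}")


if __name__ == "__main__":
    main()
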