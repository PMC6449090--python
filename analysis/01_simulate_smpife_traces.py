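#!/usr/bin/env python
"""Simulate the single-molecule PIFE experiment: surface-tethered DNA with a
binding site probed at four TF concentrations.

Generates a small example trace set from the three-state binding scheme
(unbound/low, bound/high, bound-dark/low) at the published naked-DNA rate
constants, writes a handful of example traces as TSV, and summarizes how
high-state occupancy grows with concentration.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pfkinetics import synthetic_data as syn
from pfkinetics.io import write_trace

OUT = Path(__file__).resolve().parents[1] / "results"
CONCENTRATIONS = [2.0, 5.0, 10.0, 15.0]  # nM
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    trace_dir = OUT / "example_traces"
    trace_dir.mkdir(exist_ok=True)
    scheme = syn.reb1_dna_scheme()
    print("three-state scheme, rates at c = 5 nM (s^-1):")
    print(pd.DataFrame(scheme.rate_matrix(5.0), index=scheme.state_labels,
                       columns=scheme.state_labels).round(4))

    rows = []
    rng_root = np.random.SeedSequence(SEED)
    for conc, ss in zip(CONCENTRATIONS, rng_root.spawn(len(CONCENTRATIONS))):
        rng = np.random.default_rng(ss)
        occ = []
        for j in range(25):
            tr = syn.simulate_ctmc_trace(scheme, conc, 300.0, 0.1, seed=rng)
            occ.append(tr.true_class_path.mean())
        # one short example trace per concentration for inspection
        example = syn.simulate_ctmc_trace(scheme, conc, 60.0, 0.1, seed=rng)
        write_trace(example, trace_dir / f"conc{conc:g}nM_example.tsv",
                    meta={"concentration_nM": conc, "seed": SEED})
        # steady-state bound fraction of the scheme for comparison
        q = scheme.rate_matrix(conc)
        pi = syn._stationary(q)
        rows.append({
            "concentration_nM": conc,
            "mean_high_occupancy": float(np.mean(occ)),
            "stationary_high_occupancy": float(pi[1]),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "occupancy_vs_concentration.tsv", sep="\t", index=False)
    print("\nhigh-state occupancy rises with TF concentration:")
    print(df.round(3).to_string(index=False))
    print(f"\nwrote example traces to {trace_dir} and the summary table to "
          f"{OUT / 'occupancy_vs_concentration.tsv'}")


if __name__ == "__main__":
    main()
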