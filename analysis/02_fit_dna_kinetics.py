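#!/usr/bin/env python
"""Full single-molecule kinetics pipeline on the naked-DNA scheme.

Simulates 130 traces of 300 s per concentration (2/5/10/15 nM), idealizes
each with the two-state HMM, pools dwell times, fits windowed exponential
mixtures with likelihood-ratio model selection, and extracts the binding
rate constant k_on (slope of the unbound-exit rate vs concentration) and
the pooled dissociation rate k_off.  Ground truth: k_on = 0.032 s^-1 nM^-1,
bound-state exit rate = 0.592 s^-1.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pfkinetics.io import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = PipelineConfig(
        concentrations=[2.0, 5.0, 10.0, 15.0],
        n_traces=130,
        duration_s=300.0,
        frame_interval_s=0.1,
        out_dir=str(OUT / "dna_kinetics"),
    )
    report = run_pipeline(cfg, seed=SEED)

    kon = report["k_on"]
    koff = report["k_off"]
    kd = report["apparent_kd_nM"]
    print(f"binding rate constant  k_on  = {kon['slope']:.4f} "
          f"+/- {kon['se']:.4f} s^-1 nM^-1   (truth 0.032)")
    print(f"dissociation rate      k_off = {koff['pooled_rate']:.4f} "
          f"+/- {koff['pooled_se']:.4f} s^-1      (truth 0.592; "
          f"concentration {koff['verdict']})")
    print(f"apparent K_D = k_off/k_on    = {kd['value']:.1f} "
          f"+/- {kd['se']:.1f} nM")
    for conc, block in report["per_concentration"].items():
        lo, hi = block["low"], block["high"]
        print(f"  {conc} nM: unbound-exit {lo['n_components']}-exp "
              f"{[round(r, 4) for r in lo['rates']]}, "
              f"bound-exit {hi['n_components']}-exp "
              f"{[round(r, 4) for r in hi['rates']]}")
    (OUT / "dna_kinetics_summary.json").write_text(
        json.dumps({"k_on": kon, "k_off": koff, "apparent_kd_nM": kd},
                   indent=1, default=float)
    )
    print(f"full report under {cfg.out_dir}")


if __name__ == "__main__":
    main()
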