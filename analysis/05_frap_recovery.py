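#!/usr/bin/env python
"""FRAP half-life recovery for nuclear proteins with different chromatin
engagement.

Generates noisy bleach/recovery ratio curves at the published half-lives
(pioneer factor 25.8 s, remodeler subunit 7.8 s, HMG-box protein 0.2 s) and
one immobile-protein curve (histone-like, no recovery within the window),
then fits each with the single-exponential immobile-fraction model.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pfkinetics import frap
from pfkinetics import synthetic_data as syn

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

# protein label -> (t_half s, frame interval s, post-bleach frames)
DESIGNS = {
    "Reb1": (25.8, 0.25, 480),
    "Sth1": (7.8, 0.25, 200),
    "Nhp6A": (0.2, 0.05, 60),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    root = np.random.SeedSequence(SEED)
    rows = []
    for (label, (t_half, dt, n_post)), ss in zip(
        DESIGNS.items(), root.spawn(len(DESIGNS))
    ):
        rng = np.random.default_rng(ss)
        spec = syn.FRAPSpec(t_half=t_half, depth=0.8, mobile=0.9,
                            noise_sd=0.02, frame_interval=dt,
                            n_postbleach=n_post)
        est = [
            frap.fit_frap(frap.FRAPCurve.from_frame(
                syn.simulate_frap(spec, seed=rng))).t_half
            for _ in range(25)
        ]
        rows.append({
            "protein": label, "t_half_true_s": t_half,
            "t_half_median_s": float(np.median(est)),
            "t_half_iqr_s": float(np.subtract(*np.percentile(est, [75, 25]))),
        })
        print(f"{label:6s} true t_1/2 {t_half:5.1f} s -> median fitted "
              f"{np.median(est):5.2f} s over 25 noisy curves")

    # stably incorporated protein: no recovery on the experimental time scale
    immobile = syn.FRAPSpec(t_half=3600.0, depth=0.8, mobile=1.0,
                            noise_sd=0.02, frame_interval=0.25,
                            n_postbleach=200)
    fit = frap.fit_frap(frap.FRAPCurve.from_frame(
        syn.simulate_frap(immobile, seed=np.random.default_rng(99))))
    print(f"histone-like control: flags = {fit.flags}")

    pd.DataFrame(rows).to_csv(OUT / "frap_recovery.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'frap_recovery.tsv'}")


if __name__ == "__main__":
    main()
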