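# pfkinetics

Binding and dissociation kinetics of pioneer transcription factors on DNA
and nucleosomes, from single-molecule fluorescence traces, ensemble
titrations, and FRAP recovery curves.

Most transcription factors are excluded by nucleosomes: the wrapped DNA
slashes their binding rate, and partial unwrapping accelerates their
release. Pioneer factors (in budding yeast, Reb1 and Cbf1) bind nucleosomal
sites with near-DNA affinity anyway. The kinetic explanation is
*dissociation rate compensation*: the nucleosome reduces k_on ~50–120-fold,
but the factor's dissociation rate k_off drops by a comparable factor, so
the apparent dissociation constant

    K_D = k_off / k_on

barely moves. This package implements the complete analysis chain that
establishes that result from raw-ish data, plus a synthetic-data generator
that emulates every input so the chain is testable end to end:

- `pfkinetics.synthetic_data` — Gillespie simulation of concentration-scaled
  kinetic schemes with aggregated low/high observable classes, alternating
  renewal traces with exponential-mixture dwell laws, Hill/Langmuir
  titrations, and FRAP recovery curves;
- `pfkinetics.trace_model` — trace QC and two-state hidden-Markov
  idealization (maximum-likelihood Baum–Welch + Viterbi, batched);
- `pfkinetics.dwell_analysis` — dwell-time extraction with censoring,
  dead-time/finite-movie truncated exponential-mixture MLE (continuous or
  frame-lattice likelihood), and single- vs double-exponential selection by
  likelihood ratio (χ² or parametric bootstrap);
- `pfkinetics.kinetics` — k_on from the concentration dependence of the
  unbound-exit rate (weighted linear fit), k_off from
  concentration-independence pooling, apparent K_Ds, and the
  DNA-vs-nucleosome compensation report;
- `pfkinetics.ensemble_titration` — binding-isotherm fits for S_1/2 and the
  (Ratio)_A FRET-efficiency inversion;
- `pfkinetics.frap` — recovery-curve normalization and half-life fitting
  with an immobile fraction;
- `pfkinetics.io` / `pfkinetics.cli` — trace TSV I/O, YAML pipeline
  configuration, the seeded end-to-end driver, and the `pfkin` command line.

The scientific background, model definitions, estimator details, and
numerical choices are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study's analyses on synthetic
data and write tables under `results/`. The core one:

```bash
python analysis/02_fit_dna_kinetics.py
```

simulates 130 surface-tethered DNA molecules for 300 s at each of 2, 5, 10
and 15 nM TF from the three-state scheme (unbound/low ⇄ bound/high ⇄
bound-dark/low; k_on = 0.032 s⁻¹ nM⁻¹, bound-state exit rate 0.592 s⁻¹),
idealizes every trace with the two-state HMM, pools dwell times, fits
truncated exponential mixtures with model selection, and prints:

```
binding rate constant  k_on  = 0.0309 +/- 0.0003 s^-1 nM^-1   (truth 0.032)
dissociation rate      k_off = 0.5829 +/- 0.0042 s^-1      (truth 0.592; concentration independent)
apparent K_D = k_off/k_on    = 18.8 +/- 0.2 nM
  2.0 nM: unbound-exit 1-exp [0.0618], bound-exit 1-exp [0.5841]
  5.0 nM: unbound-exit 2-exp [0.1605, 0.0231], bound-exit 1-exp [0.5822]
  ...
```

Reading: the unbound-exit rate grows linearly with concentration (its slope
is k_on; the 2-exp fits additionally resolve the ~0.02 s⁻¹
concentration-independent structural transition), the bound-exit rate does
not depend on concentration and pools to k_off, and their ratio is the
apparent K_D in nM. `analysis/03_compensation_report.py` then computes the
headline comparison from the published rate constants — a 53-fold k_on
reduction against a 130-fold k_off reduction for Reb1 (120-fold k_on for
Cbf1) — which is the compensation signature.

The same pipeline is scriptable from a shell:

```bash
pfkin run-all --config configs/reb1_dna_demo.yaml --seed 1 --out results/demo
```

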