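# Methods

`pfkinetics` analyzes how DNA-binding proteins — in particular yeast pioneer
transcription factors such as Reb1 and Cbf1 — bind and release their target
sites on naked DNA and inside nucleosomes. The central quantity is the pair
of rate constants (k_on, k_off) per substrate: their ratio k_off/k_on is the
apparent dissociation constant K_D, and the comparison of the DNA→nucleosome
fold change in k_on with that in k_off is the dissociation-rate-compensation
signature (a factor that binds a nucleosomal site ~50× slower but also leaves
~100× slower has near-unchanged affinity). This note documents the models,
the estimation procedures, the numerical choices, and what the synthetic data
can and cannot certify.

## Kinetic models

**Aggregated continuous-time Markov chain.** A `KineticScheme` is a generator
matrix over a small set of molecular states, each mapped onto one of two
observable classes (low/high fluorescence). Off-diagonal rates are
`κ_ij · c^e_ij` with `e_ij ∈ {0, 1}`: binding edges scale linearly with TF
concentration `c` (nM), dissociation and structural edges do not. Observable
class dwell distributions of such aggregated chains are phase-type (sums of
exponentials), which is how single-molecule dwell histograms acquire
multi-exponential shape from simple topologies.

The reference three-state DNA-binding scheme is U (unbound, low) ⇄ B (bound,
high) ⇄ B* (bound, structurally distinct, low), with defaults
`κ_UB = 0.032 s⁻¹ nM⁻¹`, `κ_BU = 0.58 s⁻¹`, `κ_BB* = 0.012 s⁻¹`,
`κ_B*B = 0.022 s⁻¹`. The B⇄B* edges model the concentration-independent
low⇄high transitions attributed to conformational changes of the bound
complex; `κ_B*B` is the published secondary on-rate and `κ_BB*` is the
published secondary off-rate scaled by the secondary/primary amplitude ratio
(0.036 × 25/75), which keeps the bound-state total exit rate (0.592 s⁻¹)
within 2% of the primary dissociation rate constant. That total exit rate is
the ground truth the pipeline-recovery checks compare against.

**Renewal model.** `RenewalSpec` generates alternating low/high sojourns
drawn directly from per-class exponential mixtures (≤ 2 components). Unlike
the aggregated chain, its mixture amplitudes are exactly the requested ones,
which makes it the right ground truth for amplitude-recovery tests.

**Trace synthesis.** Gillespie simulation produces the exact event path; the
camera is modeled by assigning each frame the class occupying the majority of
its window (a `midpoint` sampling alternative is available by flag). Emissions
are Gaussian per class; the default separation is 5 SD (means 1.0/1.5, SD
0.1), matching the visually well-separated traces the two-state idealization
regime assumes. Photobleaching, when enabled, truncates the trace at an
exponential time. Frame intervals default to 0.1 s for fast PIFE-like
kinetics and 1.0 s suits slow nucleosome-FRET kinetics; the acquisition
parameters of the original movies are not published, so these are package
choices. All generators draw from a `numpy` Generator seeded explicitly;
identical arguments and seed give byte-identical traces.

## Trace idealization

Traces are fit with a two-hidden-state HMM with Gaussian emissions by
maximum-likelihood Baum–Welch EM. The state count is fixed at two because the
assay observable is two-level by construction; with K fixed, the
variational-Bayes machinery used by some smFRET tools adds nothing that the
well-separated regime needs, and ML-EM is far easier to verify (the forward
likelihood and Viterbi path are tested against exhaustive path enumeration at
T ≤ 10). Auto-initialization puts the means at the 10th/90th signal
percentiles, SDs at half the overall SD, and self-transition probabilities at
0.95. The log-likelihood is non-decreasing across iterations (asserted in
tests); emission SDs are floored at 10⁻⁴ of the signal range so noiseless
traces converge instead of diverging. States are reported ordered
μ_low < μ_high. Viterbi ties are broken toward the previous frame's class,
which avoids spurious single-frame dwells. For two-channel FRET traces the
idealization observable is the uncorrected proximity ratio I_A/(I_A+I_D);
γ-type corrections do not move dwell boundaries. The EM core is batched over
equal-length traces with independent per-trace parameters, which is how a
whole concentration series is processed in one vectorized pass.

Quality control (`qc_filter`) is deterministic and reports a per-trace
reason: missing second channel, too few frames, or low SNR, where SNR is the
10–90 percentile signal separation over a lag-1-difference noise estimate.
The retention fractions of real datasets depend on criteria the package
cannot know; the filter exposes them as configuration.

## Dwell-time analysis

Consecutive same-class runs of the idealized path become dwell times
(run length × frame interval). The first and last sojourn of each trace are
censored — their true length is only bounded below — and are dropped by
default; a `keep` policy retains them as right-censored survival
contributions. Dropping is the common practice when dwells are short relative
to the movie; the truncated likelihood below absorbs the induced bias.

**Windowed mixture likelihood.** Dwell sets are fit with 1- or 2-component
exponential mixtures by maximizing

    Σ_j log f(t_j) − n·log[F(t_max) − F(t_min)],

the dead-time-and-finite-movie truncated likelihood (t_min defaults to one
frame interval, t_max to the movie length). For continuous-valued durations
this is the standard MEMLET-style objective. For durations quantized to the
frame grid the continuous density is wrong in a specific, consequential way:
a mixture component with a very fast rate can park its mass on the first
lattice point and win likelihood it has not earned (we observed this ghost
component even on ground-truth paths). The fitter therefore accepts a
`lattice_dt` and switches to the interval-censored form, scoring an observed
duration t as the probability mass on [t − Δt/2, t + Δt/2); the pipeline
always passes the frame interval. Rates are additionally capped at 5/t_min —
components decaying essentially entirely below the dead time are
unidentifiable ridge directions, not physics.

Optimization: single-exponential fits use the closed form 1/mean when no
window or censoring applies, otherwise a bounded scalar search; two-component
fits run Nelder–Mead from 7 deterministic starts (method-of-moments center,
spread perturbations, and two near-degenerate starts that guarantee the
two-component optimum is never below the nested single-exponential one).
Components are reported sorted by amplitude descending; "primary" means
largest amplitude, not fastest rate — on DNA the primary dissociation
component is the faster one, on nucleosomes the slower one, and the
definition must not presuppose either. Amplitudes pinned to a boundary
(< 0.01) are flagged `effectively_single_exponential`. Parameter SEs come
from a nonparametric bootstrap over dwells when requested; per-concentration
series weights use the asymptotic SE k/√(a·n) instead, which is accurate at
the pipeline's dwell counts and orders of magnitude cheaper.

In the pipeline the dead time is raised to 2 frames
(`dead_time_frames = 2`): single-frame dwells are dominated by idealization
blips (isolated misassigned frames), and the truncated likelihood accounts
exactly for the discarded mass.

**Model selection.** Single vs double exponential is decided by
Λ = 2(logL₂ − logL₁). The default refers Λ to χ² with df = 2 (one extra rate
plus one amplitude). Mixture LRTs are boundary-non-regular, so a parametric
bootstrap mode (simulate from the fitted single-exponential null inside the
same window and lattice, refit both models, compare Λ) is provided as the
rigorous alternative; the χ² default is kept because it is the conventional
reading of "log-likelihood ratio test" in this literature and is, if
anything, conservative. Λ is scale-pivotal for exponential data, which the
test suite exploits to calibrate the type-I error check with a single null
simulation.

## Rate constants and the compensation report

Unbound-class exit rates are regressed on concentration by weighted least
squares (weights 1/SE²); the slope is k_on (s⁻¹ nM⁻¹). The intercept is free
by default — it absorbs any concentration-independent low→high process — with
a through-origin mode by flag. Parameter covariance is the known-variance
form (XᵀWX)⁻¹, not residual-rescaled, because the weights are true inverse
variances. When the chosen component count differs across concentrations,
single-component fits feed both the fast and slow candidate series, and the
component whose rate has the highest Pearson correlation with concentration
is taken as binding; the other is reported as a structural transition rate.
Bound-class exit rates are tested for concentration independence (slope-vs-0
z-test at α = 0.05) and pooled by inverse variance into k_off. K_D = k_off /
k_on with first-order error propagation (validated against Monte Carlo within
10%).

The compensation report assembles, per factor, k_on and k_off for DNA and
nucleosome substrates, the fold reductions, apparent K_Ds, and — because
surface tethering depresses absolute on-rates similarly for both substrates —
compares the single-molecule relative affinity K_D(nuc)/K_D(DNA) with the
ensemble S_1/2 ratio. Headline folds are rounded to 2 significant figures in
the human-readable table; machine output keeps full precision.

## Ensemble titrations and (Ratio)_A

Titrations (EMSA fraction bound, FRET efficiency, PIFE fold) are fit to
f(c) = f0 + (f1 − f0)·cⁿ/(S₁/₂ⁿ + cⁿ) by least squares with S₁/₂ starts
log-spaced over the concentration range. Concentrations are normalized by
their maximum before fitting, which makes Ŝ₁/₂ exactly equivariant under
rescaling of the concentration axis. The Hill exponent is fixed at 1 by
default — the study's isotherms are simple — and can be freed. A flat
response is rejected with a "no binding signal" warning rather than fit.

Ensemble FRET efficiency uses the (Ratio)_A method: E = [(F_AD/F_AA) −
ε_A(Dex)/ε_A(Aex)] / (d⁺ · ε_D(Dex)/ε_A(Aex)), with F_AD the sensitized
acceptor emission (donor bleed-through already subtracted), F_AA the directly
excited acceptor emission, and d⁺ the donor-labeling fraction. The shipped
extinction-ratio defaults are placeholders for Cy3/Cy5 at 510/610 nm
excitation; real analyses must supply instrument values. The inversion
composed with its forward model is the identity over E ∈ [0, 1] for any valid
ratios (property-tested); values outside [−0.05, 1.05] are clamped with a
warning.

## FRAP

Recovery curves are the bleached/unbleached region intensity ratio (which
cancels global acquisition photobleaching), normalized so the pre-bleach
ratio averages 1. Post-bleach recovery is fit with
R(t) = (1 − d) + d·m·(1 − e^(−t·ln2/τ½)): bleach depth d, mobile fraction m,
half-life τ½. A single exponential with an immobile fraction is the most
complex model the published protocol can identify; diffusion–reaction FRAP
models are out of scope. Time zero is the bleach event and frames are stamped
at their midpoints, so the first post-bleach sample sits at Δt/2. Because a
flat curve fits the model degenerately (as an instant, tiny recovery), the
no-recovery flag is decided from the data — early-vs-late post-bleach
comparison against frame-to-frame noise — in addition to the fitted
parameters (τ̂½ > 3× the window, or negligible recovered amplitude).

## Problem sizes and what the tests show

The pipeline-recovery checks run the full chain (simulate → QC → HMM →
Viterbi → dwells → mixture MLE → selection → series → rates) at the published
naked-DNA rate constants: 130 traces × 300 s × 0.1 s frames per concentration
(2/5/10/15 nM) in the acceptance script, and a reduced 30 × 150 s
configuration inside the test suite; both recover the bound-state exit rate
well within 15% (typically within 2%) and k_on within ~10%.
FRAP recovery uses 50 replicate curves at 0.25 s frames with 480 post-bleach
frames (120 s ≈ 4.7 half-lives, chosen so the plateau is identifiable) and
noise SD 0.02.

Passing these tests certifies the estimators against their own generative
assumptions — Markovian kinetics, Gaussian emissions, static levels, majority
-vote discretization. Real recordings add baseline drift, intensity
heterogeneity between molecules, blinking and bleaching of dyes, and
non-Markovian memory, none of which the generator emulates; the QC filter and
dead-time handling mitigate but do not model them. Agreement on synthetic
data therefore validates the computation, not the photophysics.

## Known limitations

- Exactly two observable classes; no three-state idealization or model-count
  selection at the HMM level.
- Mixtures are capped at two exponential components; no stretched-exponential
  or gamma dwell models.
- The EMSA module consumes fraction-bound numbers; gel densitometry is out of
  scope, as are spot detection and image registration.
- The χ²(df = 2) default for the LRT is conventional rather than exact; use
  the bootstrap mode when calibration matters.
- The rate cap 5/t_min means sub-dead-time kinetics are deliberately
  unrecoverable; choose the frame interval accordingly.
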