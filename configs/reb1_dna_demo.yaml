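# Demo pipeline configuration: small synthetic smPIFE-style dataset at the
# naked-DNA binding scheme.  Runs in well under a minute; for rate constants
# with publication-grade precision raise n_traces and duration_s (see
# analysis/02_fit_dna_kinetics.py, which uses 130 traces of 300 s).
concentrations: [2.0, 5.0, 10.0, 15.0]
n_traces: 20
duration_s: 120.0
frame_interval_s: 0.1
k_on: 0.032
k_off: 0.58
k_struct_out: 0.012
k_struct_back: 0.022
emission_mean_low: 1.0
emission_mean_high: 1.5
emission_sd: 0.1
input_dir: null
min_snr: null
hmm_tol: 0.0001
hmm_max_iter: 200
censor_policy: drop
dead_time_frames: 2
selection_mode: chi2
alpha: 0.05
unbound_class: low
kon_through_origin: false
seed: 0
out_dir: null
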