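# Full-defaults pipeline configuration (study conditions).
# Any subset of keys may be overridden; CLI flags win over this file.
seed: 0
out_dir: renperf_out

# FAIR-ASL quantification
ti: 1.2          # inversion (inflow) time, s
t1: 1.14         # tissue longitudinal relaxation time, s
lambda_bt: 0.8   # blood-tissue water partition coefficient, ml/g

# DCE deconvolution
dt: 0.9                  # volume spacing, s
n_baseline: 15           # pre-contrast volumes
first_pass_volumes: 50   # analysis window (60 for late bolus washout)
threshold_fraction: 0.15 # truncated-SVD threshold for noisy data

# agreement statistics
ddof_groups: 1   # sample SD for group summaries
ddof_diffs: 0    # population SD for difference/repeatability summaries

# phantom simulation
noise_sigma: 0.0       # ASL per-frame noise sd (signal units)
dce_noise_sigma: 0.0   # DCE per-volume noise sd (signal units)
n_pairs: 30            # ASL tag-control pairs (90 frames total)
n_volumes: 120         # simulated DCE volumes before truncation
n_slices: 3            # DCE slices
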