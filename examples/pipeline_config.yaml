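# Full-pipeline configuration for `ictalcoh report <this file>`.
# Either point scalp_path/seeg_path (+ coords_path, soz_path, so_marker)
# at recorded files, or give a simulate block as below.

simulate:
  eccentricity: 0.8      # source depth as a fraction of the head radius
  seed: 7
  config:
    fs: 256.0            # Hz
    duration: 36.0       # s
    imposed_lag: 100.25  # samples; recovered by the alignment stage
    seed: 7

# epoch around the seizure-onset marker (filled from the simulation)
pre: 20.0                # s before onset
post: 10.0               # s after onset

band: [5.0, 100.0]       # Hz, Hamming windowed-sinc FIR
transition: 2.0          # Hz

ica_seed: 0
n_components: 8
ica_max_iter: 80

alpha: 0.05              # surrogate significance level
n_surrogates: 200        # white-noise realizations for calibration
surrogate_seed: 0
outlier_k: 5.0           # Ns > median + k*IQR selects outlier pairs

component: max_sna_soz   # "auto" | integer override | "max_sna_soz"
outdir: pipeline_run
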