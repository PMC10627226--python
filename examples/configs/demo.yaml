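# Full-scale demo: 4 maturity groups x 5 day/night temperatures x
# 5 replicate pots x 15 measurements = 1,500 simulated transients.
# Run:  ojip all --config examples/configs/demo.yaml --seed 1 --out scratch/demo
seed: 1
alpha: 0.05
use_replicate_means: true
output_dir: scratch/demo
heatmap: true
table_parameters: [phi_Po, phi_Do, phi_Eo, delta_Ro, PI_abs, rc_density]
simulation:
  axis: temperature
  levels: ["22/14", "26/18", "30/22", "34/26", "40/32"]
  maturity_groups: ["0", "III", "IX", "X"]
  n_reps: 5
  n_meas: 15
  harvests: true
  # treatment scenarios: multiplicative shifts of the control kinetics
  # (illustrative/directional, not fitted to any measured dataset)
  scenarios:
    "22/14": {d_F0: 1.10, d_Fm: 0.85, d_IP: 0.45}          # chilling
    "26/18": {}                                             # control
    "30/22": {d_Fm: 0.97}
    "34/26": {d_F0: 1.10, d_Fm: 0.88, d_IP: 0.70, d_Kband: 0.08}
    "40/32": {d_F0: 1.20, d_Fm: 0.75, d_IP: 0.60, d_Kband: 0.15}  # severe heat
  preset:
    F0_base: 500.0
    Fm_base: 2500.0
    phase_amplitudes: [0.5, 0.3, 0.2]
    phase_taus: [250.0, 5000.0, 60000.0]
    noise_cv: 0.02
    replicate_sd: 0.05
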