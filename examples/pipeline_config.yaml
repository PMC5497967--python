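# Demo end-to-end pipeline configuration: simulate a 16-channel basket
# recording with planted coupling, remove the synthetic ventricular far
# field, estimate windowed mutual information, and sweep the default
# density grid (0.10-0.30, step 0.01 -> 21 metric rows).
#
#   afnet run --config examples/pipeline_config.yaml --out demo_run
seed: 1
output_dir: demo_run
simulation:
  n_splines: 4
  per_spline: 4
  model: clustered
  n_bridges: 6
  triangle_coupling: 0.3
  bridge_coupling: 0.4
  duration_s: 60.0
  ventricular: true
preprocessing:
  window_s: 10.0
  n_windows: 5
  subtract: true
ksg:
  k: 4
null_ensemble:
  ensemble_size: 100
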