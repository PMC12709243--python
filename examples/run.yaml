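# Full-pipeline configuration for `segfcs run --config examples/run.yaml`
# (simulated input; replace `simulation` with `input_path: carpet.tif` plus a
# `meta:` block or a .meta.json sidecar to analyze microscope data)
out_dir: scratch/example_run
simulation:
  n_particles: 250
  n_lines: 42000          # 30 s at 1400 Hz
  D_free: 3.8             # um^2/s
  k_on: 20.0              # 1/s inside the damage strip
  tau_B: 0.8              # s
  bleach_rate: 0.05       # 1/s at beam centre
  power_factor: 1.0
  seed: 1
segment_duration: 4.0     # s
in_threshold: 0.8
out_threshold: 0.5
w0: 0.3                   # um, detection-spot lateral 1/e^2 radius
kinetics_bin: 128         # lines per block of the damage-region trace
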