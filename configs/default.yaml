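# Default end-to-end run: 150-trial pole-detection session, 128x128 movie,
# 20 planted dendrites, sparse-NMF segmentation with K = 30.
task:
  n_trials: 150
  frame_rate_hz: 4.0
population:
  n_dendrites: 20
segmentation:
  K: 30
analysis:
  alpha: 0.05
seeds:
  session: 0
  rendering: 1
  segmentation: 2
  control_windows: 3
frame_size_px: 128
out_dir: results/default_run
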