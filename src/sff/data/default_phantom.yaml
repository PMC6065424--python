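# Pinned default acceptance phantom: 128x128, 40 frames at 20 f/s, one
# accumulating blob (radius 10 px), one static bright artifact band,
# translation-only random-walk motion, seed 1234.
shape: [128, 128]
n_frames: 40
fps: 20.0
background: 0.25
tissue_texture_amp: 0.04
tissue_texture_sigma: 4.0
speckle_scale: 1.0
speckle_smooth_sigma: 1.0
speckle_decorrelation: 0.15
gain_jitter_std: 0.03
electronic_noise_std: 0.005
blobs:
  - center: [84.0, 70.0]
    radius: 10.0
    peak_amplitude: 0.35
    rate: 0.08
artifacts:
  - row_start: 40
    row_stop: 48
    amplitude: 0.4
    col_start: 30
    col_stop: 110
motion: random_walk
motion_step: 1
motion_bound: 6
seed: 1234
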