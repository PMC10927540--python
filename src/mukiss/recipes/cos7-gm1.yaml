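# Punctual labeling of GM1 on a live COS-7 plasma membrane: 0.7 s
# labeling frame, faster spreading than the model membrane.
# Ground truth D = 0.32 μm²/s (reference sd 0.13, n = 8).
kind: punctual
spot:
  amplitude: 120.0
  sigma0: 0.4247
  center: [9.6, 9.6]
  D: 0.32
psf: {wavelength_nm: 488.0, na: 1.0}
noise: {read_sd: 2.0, background: 5.0}
pixel_size: 0.2
frame_interval: 0.7
n_frames: 18
n_pixels: 96
replicates: 8
reference: {mean: 0.32, sd: 0.13}
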