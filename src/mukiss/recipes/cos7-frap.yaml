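# FRAP on the live COS-7 membrane.  At D = 0.35 μm²/s a 1 μm hole
# refills within ~1 s, so the recovery is recorded at 130 ms frames
# (late frames legitimately fall below the noise floor and are
# excluded by the per-frame flags).  Reference sd 0.14, n = 8.
kind: frap
prebleach_level: 500.0
bleach:
  amplitude: 450.0
  sigma0: 0.4247
  center: [9.6, 9.6]
  D: 0.35
psf: {wavelength_nm: 488.0, na: 1.0}
noise: {read_sd: 2.0, background: 5.0}
pixel_size: 0.2
frame_interval: 0.13
n_frames: 30
n_prebleach: 5
n_pixels: 96
replicates: 8
reference: {mean: 0.35, sd: 0.14}
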