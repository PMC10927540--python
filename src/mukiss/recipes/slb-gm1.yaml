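# Punctual labeling of GM1 (CTxB-AF488) on a supported lipid bilayer:
# a 1 μm-footprint spot delivered in one 130 ms frame, then spreading
# by free 2D diffusion.  Ground truth set to the membrane estimate
# D = 0.048 μm²/s (reference sd 0.017 over n = 30 replicates).
kind: punctual
spot:
  amplitude: 120.0        # peak counts; ~5x dimmer than the FRAP plateau signal
  sigma0: 0.4247          # μm; 1 μm FWHM labeling footprint
  center: [4.8, 4.8]      # μm
  D: 0.048                # μm²/s ground truth
psf: {wavelength_nm: 488.0, na: 1.0}
noise: {read_sd: 2.0, background: 5.0}
pixel_size: 0.1           # μm
frame_interval: 0.13      # s
n_frames: 30
n_pixels: 96
replicates: 30
reference: {mean: 0.048, sd: 0.017}
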