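# FRAP on the same supported-bilayer system: uniform CTxB-AF488
# plateau, 1 μm-diameter bleach spot, recovery recorded at 130 ms.
# Ground truth D = 0.045 μm²/s (reference sd 0.008, n = 30).
kind: frap
prebleach_level: 500.0    # plateau counts
bleach:
  amplitude: 450.0        # bleach depth, counts
  sigma0: 0.4247          # μm; 1 μm FWHM bleach spot
  center: [4.8, 4.8]
  D: 0.045
psf: {wavelength_nm: 488.0, na: 1.0}
noise: {read_sd: 2.0, background: 5.0}
pixel_size: 0.1
frame_interval: 0.13
n_frames: 30
n_prebleach: 5
n_pixels: 96
replicates: 30
reference: {mean: 0.045, sd: 0.008}
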