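# Two-channel punctate colocalization emulating transferrin (A)
# labeled onto clathrin structures (B); the design solves spot
# amplitudes so the measured Mander's coefficients equal
# M1 = 0.71 (Tf-in-clathrin) and M2 = 0.62 (clathrin-in-Tf).
kind: coloc
design:
  target_m1: 0.71
  target_m2: 0.62
  n_common: 24
  n_a_only: 10
  n_b_only: 14
  spot_sigma: 0.15        # μm pre-PSF
  amplitude: 300.0
  threshold: 30.0         # fixed absolute mask threshold, counts
  background_subtraction: 8.0   # background + ~3 sd of the noise model
psf: {wavelength_nm: 561.0, na: 1.0}
noise: {read_sd: 1.0, background: 2.0}
pixel_size: 0.1
n_pixels: 128
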