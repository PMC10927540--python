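# Extended peripheral labeling: a static crescent-like band at the
# cell edge with dye-enriched clusters drifting at ~nm/s, imaged every
# 5 s for >900 s.  The primary cluster drifts at 7.5 nm/s; a second,
# static cluster provides a vertical reference ridge in the kymograph.
kind: extended
band: {y_center: 2.0, sigma: 0.8, intensity: 80.0}
clusters:
  - {position: [1.5, 2.0], speed: 0.0075, direction: [1.0, 0.0],
     amplitude: 120.0, sigma: 0.25}
  - {position: [11.0, 2.0], speed: 0.0, direction: [1.0, 0.0],
     amplitude: 100.0, sigma: 0.25}
psf: {wavelength_nm: 488.0, na: 1.0}
noise: {read_sd: 2.0, background: 5.0}
pixel_size: 0.1
frame_interval: 5.0       # s
n_frames: 190             # 945 s span
n_pixels: [40, 128]       # (rows, cols): 4 x 12.8 μm field
kymograph:
  path: [[0.3, 2.0], [12.5, 2.0]]
  line_width: 0.5         # μm
  feature_window: [0.2, 2.2]   # arc-length range of the drifting ridge at t=0
reference: {speed_nm_s: 7.5}
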