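# Labeled receptor clusters in a 15 x 15 μm² membrane patch: mobile
# clusters coalesce on contact so the count decays and the mean size
# grows over several minutes.
kind: clusters
n0: 40
D_cluster: 0.01           # μm²/s cluster mobility
coalescence_radius: 0.4   # μm
field_size: 15.0          # μm
duration: 360.0           # s
frame_interval: 5.0
pixel_size: 0.15
noise: {read_sd: 1.0, background: 2.0}
initial_intensity: 2000.0 # integrated counts per initial cluster
initial_sigma: 0.2        # μm
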