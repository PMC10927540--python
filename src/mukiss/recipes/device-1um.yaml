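# 1 μm inner-diameter aperture pair at rim-touching separation,
# Q_ratio = 0.3; the narrow-brush configuration used for punctual
# membrane labeling.
geometry:
  aperture_inner_diameter_inj: 1.0
  aperture_inner_diameter_asp: 1.0
  wall_thickness: 1.0
  tip_separation: null
  in_plane_angle: 35.0
  tip_height: null
  substrate_present: false
flow:
  Q_inj: 0.048
  Q_asp: 0.16
  viscosity: 0.9544
  temperature: 22.0
  density: 997.8
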