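# 6 μm inner-diameter aperture pair (pulled micropipettes with 1 μm
# walls), Q_inj = 0.16 nl/s at Q_ratio = 0.3.
geometry:
  aperture_inner_diameter_inj: 6.0
  aperture_inner_diameter_asp: 6.0
  wall_thickness: 1.0
  tip_separation: null
  in_plane_angle: 35.0
  tip_height: null
  substrate_present: false
flow:
  Q_inj: 0.16
  Q_asp: 0.5333333333333333
  viscosity: 0.9544
  temperature: 22.0
  density: 997.8
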