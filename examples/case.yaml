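# Coiled side-wall aneurysm, normal hematocrit, coarse desk-scale settings.
name: coiled_sac_hct40
geometry:
  vessel_diameter: 3 mm
  vessel_length: 16 mm
  dome_diameter: 5 mm
  neck_width: 2.5 mm
  mesh_size: 0.4 mm
  boundary_layer_layers: 3
  boundary_layer_growth: 1.3
waveform:
  profile: default_mca
  period: 0.8 s
  mean_velocity: 0.25     # m/s
  peak_velocity: 0.5      # m/s, reached at peak systole (t = 0.24 s)
rheology:
  hematocrit: 0.40
coil:
  porosity: from_coil     # or a number in (0, 1]; 1.0 = no coil
  coil:
    wire_diameter: 0.254 mm
    length: 30 cm
    sac_volume: 103.87 mm^3
  permeability: table     # porosity -> permeability from the reference table
solver:
  dt: 0.005 s
  cycles: 3
  snapshot_stride: 4
  density: 1060.0         # kg/m^3
sweep:                    # used by `aneuflow sweep`
  hematocrits: [0.35, 0.40, 0.45]
  porosities: [0.75, 0.85, 1.0]
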