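# Scenario presets for the synthetic-eye cohort generator.
#
# Shared physics defaults live under `defaults`; each preset overrides what
# its scenario changes.  Lengths in mm, temperatures in K, viscosity in Pa*s,
# mesh size in nm, times in hours.  `diameter_range` spans the globe sizes
# recorded for each model.  The effective mesh size for pig/human scenarios
# (20 nm) is far below the 550 nm literature value for bovine vitreous: the
# intact-globe distribution data argue the pig/human mesh is much smaller,
# and this value makes the hindrance factor meaningfully size-selective
# across the dextran panel.  `plasmin` multiplies the mesh size (partial
# enzymatic loosening of the network).
defaults:
  grid_spacing: 0.1
  padding: 2.0
  injection_offset: 4.0
  needle_depth: 0.25
  bolus_sigma: 1.0
  bolus_mass: 1.0
  viscosity: 0.002
  mesh_size: 20.0
  render:
    gain: 200000.0
    background_level: 20.0
    noise_sigma: 2.0
    vignette_strength: 0.0

presets:
  ex_vivo_5dye:
    model: "ex vivo pig"
    dyes: ["3 kDa", "40 kDa", "70 kDa", "500 kDa", "2 MDa"]
    times: [24.0, 48.0]
    temperature: 277.15
    diameter_range: [19.93514, 25.62603]
    randomize_side: true
  in_vivo_2dye:
    model: "in vivo pig"
    dyes: ["40 kDa", "2 MDa"]
    times: [48.0]
    temperature: 310.15
    diameter_range: [18.65658, 25.42192]
    injection_offset: 3.5
    randomize_side: false
    side: temporal
  plasmin:
    model: "ex vivo pig plasmin"
    dyes: ["40 kDa", "2 MDa"]
    times: [24.0]
    temperature: 277.15
    diameter_range: [19.93514, 25.62603]
    randomize_side: false
    side: temporal
    mesh_multiplier: 3.0
  human_bursa:
    model: "ex vivo human"
    dyes: ["40 kDa", "2 MDa"]
    times: [24.0]
    temperature: 277.15
    diameter_range: [21.9114, 25.94056]
    randomize_side: false
    side: temporal
    bursa:
      center_frac: [0.0, 0.55]   # (x, y) as fractions of the eye radius
      radius_frac: 0.18
      n_vertices: 16
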