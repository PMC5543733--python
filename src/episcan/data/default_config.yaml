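# Default pipeline configuration. Every numeric decision the predictor makes
# lives here: scale choices, window sizes, discretization bins, composite
# weights and selection thresholds. Values can be overridden by a user config
# file (same structure, partial trees allowed) or CLI flags.
seed: 0

scales:
  hydrophilicity:
    name: hopp-woods        # kyte-doolittle selectable; it is sign-inverted on
    window: 7               # load so that high = hydrophilic holds uniformly
  surface:
    name: emini-surface
    anchor: first           # hexapeptide value assigned to the window's first residue
  flexibility:
    name: flexibility
    window: 7
    weights: [0.25, 0.4375, 0.625, 1.0, 0.625, 0.4375, 0.25]

secstruct:
  helix_cutoff: 1.03
  strand_cutoff: 1.05
  turn_cutoff: 7.5e-5
  gor_decision_constants: {H: 0.0, E: 0.0, T: 0.0, C: 0.0}

discretization:
  levels: [-0.6, -0.3, -0.1, 0.0, 0.1, 0.3, 0.6]
  # value <= threshold stays in the lower bin
  hydrophilicity_thresholds: [-1.5, -0.75, -0.25, 0.25, 0.75, 1.5]
  surface_thresholds: [0.5, 1.5, 4.0, 10.0, 25.0, 60.0]
  flexibility_thresholds: [0.96, 0.98, 1.0, 1.02, 1.04, 1.06]
  state_scores: {T: 0.6, C: 0.3, E: -0.3, H: -0.6}

antigenic_index_weights:
  hydrophilicity: 0.3
  surface: 0.15
  flexibility: 0.15
  structure_cf: 0.2
  structure_gr: 0.2

selection:
  min_length: 8
  ai_threshold: 0.15
  hydrophilicity_min: 0.0
  surface_min: 1.0
  flexibility_min: 1.0
  max_rigid_fraction: 0.3
  gap_merge: 1
  forbidden_regions: []     # list of [start, end], 1-based inclusive; off by default

conservation:
  gap_policy: exclude
  variable_threshold: 1.0

verify_checksums: true
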