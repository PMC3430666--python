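# Example simulation configuration (all values shown are the defaults
# except where noted).  Distances are simulation units: 1 unit = 10 um.
motion:
  sigma_body: 0.03      # per-body Brownian jiggle, units/step
  sigma_centre: 0.04    # shared whole-cell Brownian step, units/step
  v_edge: 0.04          # leading-edge drift, units/step
  p_new_edge: 0.08      # per-step chance of a new edge direction
  r_cell: 1.5           # cell radius (15 um)
  R_field: 50.0         # field radius (500 um)
exclusion:
  p_repel: 0.25         # chance an overlapping pair is pushed apart
  k_repel: 0.5          # fraction of overlap depth removed per event
  mode: BASIC           # ENHANCED for increased contact repulsion
adhesion:
  unhook: 5.0e-5        # per-step hook breakage probability
  seize: inf            # strengthening width in steps; inf = disabled
  hook_range: 0.3       # body capture distance, units
  p_hook: 0.2           # per-step formation chance per eligible pair
  like_type_only: true  # differential adhesion (like binds like)
  k_hook: 0.5           # pull strength of a link
  contact_dist: 0.0     # resting separation of linked bodies
engine:
  n_cells: 500          # not above the packing limit (1007)
  red_fraction: 0.5
  n_steps: 10000
  snapshot_every: 100
  seed: 1
  init_mode: RANDOM_MIX # or SPLIT_HALVES
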