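# Vapour Col (Deception Island) chinstrap colony replication configuration.
# Surveyed-zone counts, guano volumes, water compartment and global-scenario
# constants are the published field values for this rookery.
zone_table: "builtin:vapour_col_zones.csv"
breeding_days: 120
guano:
  fe_conc_mg_per_g: [3.0, 1.4]
  dry_fraction: 0.4
  layer_thickness_m: 0.02
  wet_density_kg_m3: 1088.6
  excretion_rate_g_per_ind_day: 84.4
guano_volumes_m3:
  colony: 380.2
  northern_tip: 87.4
water:
  surface_area_m2: 40000.0
  mean_depth_m: 2.0
  fe_conc_mg_per_L: 0.324
season:
  breeding_days: 120
  nonbreeding_days: 245
  breeding_release_eff: 0.10
  nonbreeding_release_eff: 1.0
population:
  n_individuals: 8.0e+6
npp:
  areas_m2:
    southern_ocean: 2.0e+13
    antarctic_peninsula: 4.5e+12
  fraction_levels: [0.25, 0.5, 0.75]
  fe_c_ratio_umol_per_mol: 3.0
  comparisons_t_fe_per_yr:
    baleen_whales: 1200.0
propagation:
  mode: first_order
  draws: 100000
  seed: 20230411
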