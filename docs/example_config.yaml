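# Experiment configuration schema for `mpaconnect run/metrics/report/generate-fields`.
# Any field of ScenarioSpec, GridSpec and TransportConfig may be set here;
# unset fields take the library defaults.

scenario:
  name: rcp85_demo
  # meridional SST pattern (degC): warm tropical pool grading to cooler
  # subtropical water; kinds: constant | linear | tanh
  sst: {kind: tanh, t0: 26.0, amplitude: 2.6, lat_mid: -14.0, lat_scale: 4.0}
  summer_offset: 3.0          # future-minus-historical warming, degC
  winter_offset: 4.0
  current_preset: coastal_shelf_system   # uniform | solid_body_rotation | zonal_jet | coastal_shelf_system
  core_speed: 0.5             # m/s, boundary-current core
  jet_width: 2.0              # degrees
  shelf_speed: 0.1            # m/s, weak inshore flow
  current_noise: 0.05         # m/s, smooth seeded perturbation
  sst_noise: 0.2              # degC

grid:                         # study box at 0.5 degree resolution
  lon_min: -70.0
  lon_max: -20.0
  lat_min: -30.0
  lat_max: 10.0
  n_lon: 101
  n_lat: 81
  time_step: 3.0              # hours between stored field snapshots
  n_times: 482                # must cover release schedule + PLD

# registry: path/to/sites.csv  # omit to use the packaged nine-site registry

years: [2092, 2093, 2094, 2095, 2096, 2097, 2098, 2099]
seasons: [summer, winter]
windows: [non_acclimated, acclimated]

total_release: 70000          # eggs per season-year experiment
events_per_season: 2          # release events (start of each season month)
# per_site_counts: [213, 530, 247, 123, 932, 1298, 824, 1221, 692]  # explicit mode

transport:
  time_step_h: 1.0            # RK4 step
  pld_days: 60.0              # pelagic larval duration
  egg_phase_h: 24.0
  release_depth_max: 5.0      # m; eggs spawn in the first metres
  vertical_mode: surface_layer
  log_every_h: 12.0           # trajectory logging cadence

master_seed: 0                # overridden by --seed
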