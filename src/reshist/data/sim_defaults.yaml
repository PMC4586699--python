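sim.abbrev_rate: 0.15
sim.annual_move_prob: 0.117
sim.city_extent_ft: 50000.0
sim.drift_years: 1.4
sim.dropout_rate: 0.05
sim.min_city_name_distance: 8
sim.min_street_name_distance: 6
sim.n_cities_per_state: 6
sim.n_states: 8
sim.n_streets_per_city: 12
sim.n_subjects: 1000
sim.p_move_same_city: 0.4
sim.p_move_same_state: 0.4
sim.point_jitter_ft: 25.0
sim.recall_depth: 3
sim.seed: 0
sim.tuning_sample_size: 100
sim.typo_max_edits: 2
sim.typo_rate: 0.05
sim.update_lag_probs:
- 0.6
- 0.3
- 0.1
sim.window_end: 2013
sim.window_start: 1995
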