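{
  "dmaf_variant": "ratio_linear",
  "error_rate": 0.001,
  "hd_size": 130,
  "lo_size": 13,
  "master_seed": 1,
  "n_folds": 5,
  "ne_prediction": 1000.0,
  "panel_maf_min": 0.05,
  "recombination_scale": 100.0,
  "scenarios": [
    "S80",
    "S60",
    "S40",
    "TWO_STEP"
  ],
  "sim": {
    "chromosome_length_bp": 10000000,
    "mutation_rate": 1e-07,
    "n_candidate_sites": 4000,
    "n_generations": 300,
    "n_sample_individuals": 50,
    "population_size_diploid": 100,
    "recombination_rate_per_bp": 1e-08,
    "seed": 0
  }
}
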