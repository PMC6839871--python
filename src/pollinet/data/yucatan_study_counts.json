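{
  "n_sites": 9,
  "insect_species_by_order": {"Diptera": 26, "Hymenoptera": 27, "Lepidoptera": 20},
  "total_pairwise_interactions": 685,
  "total_floral_visits": 14255,
  "total_flowers": 516609,
  "site_visit_totals_range": [504, 3335],
  "plant_species_range": [8, 17],
  "visitor_species_range": [22, 38],
  "honeybee_visit_share_pct": 57.5
}
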