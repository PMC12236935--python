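# Demo run: one medical-waste incinerator, four throughput/control scenarios,
# synthetic 25-tract study area and 240 hours of meteorology.
seed: 7
domain_radius_m: 50000
urban_population: 565000
study_area:
  n_tracts: 25
meteorology:
  n_hours: 240
  prevailing_direction_deg: 270
covariates:
  noise_sd: 5.0
  planted_coefficients:
    no_high_school_diploma: 9.86
    housing_cost_burden: 4.44
    limited_english: -13.58
grid:
  n_directions: 36
  n_rings: 40
  flagpole_m: 2.0
exposure_assignment: per_receptor
facilities:
  - id: medical_waste_incinerator
    location_m: [0.0, 0.0]
    stack:
      height_m: 30.0
      diameter_m: 1.2
      exit_velocity_ms: 15.0
      exit_temperature_k: 450.0
scenarios:
  - label: typical_controlled
    facilities:
      - {id: medical_waste_incinerator, throughput_tons: 26000, condition: controlled}
  - label: typical_uncontrolled
    facilities:
      - {id: medical_waste_incinerator, throughput_tons: 26000, condition: uncontrolled}
  - label: max_controlled
    facilities:
      - {id: medical_waste_incinerator, throughput_tons: 56000, condition: controlled}
  - label: max_uncontrolled
    facilities:
      - {id: medical_waste_incinerator, throughput_tons: 56000, condition: uncontrolled}
savings_pairs:
  - [typical_uncontrolled, typical_controlled]
  - [max_uncontrolled, max_controlled]
disparity_scenarios:
  - typical_controlled
  - typical_uncontrolled
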