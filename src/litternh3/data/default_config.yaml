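# Default pipeline configuration: the factorial chamber study conditions.
output_dir: runs/litternh3
seed: 20230675

design:
  bed_types: [wood_shavings, coffee_husks]
  temperatures: [25, 30, 35, 40]
  n_replicates: 3

synthetic:
  # sd multiplier on each published equation's SEE for the litter variables
  noise_scale: 1.0
  # response noise: Gaussian sd as a fraction of the cell mean
  response_noise_frac: 0.05

physchem:
  # Freundlich partition coefficient (L/kg) and dissociation constant —
  # placeholder magnitudes, set from measurements for real litter
  kf: 1.0
  kd0: 1.0e-9
  rho_water: 1.0

smdae:
  sponge_diameter_m: 0.20
  exposure_s: 86400  # 24 h

modeling:
  alpha: 0.05
  candidate_terms: ["1", "T", "T2", "T3", "C", "C2", "C3"]

adequacy:
  n_sim: 1000
  split: 0.5
  r2_method: pearson

units:
  flux_mg: false  # report SMDAE flux in g·m⁻²·s⁻¹ (true → mg)
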