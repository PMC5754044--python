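# FSA-Ofcom nutrient profile model (2004/05) component cut-points.
# Each component lists ascending cut-points per 100 g edible weight;
# a component's points = number of cut-points strictly exceeded.
# The fruit/veg/nut component maps its threshold count through fvn_point_map
# (crossing >40% earns 1 point, >60% 2 points, >80% the maximum 5 points).
a_points:
  energy_kj: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
  satfat_g: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  sugars_g: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
  sodium_mg: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
c_points:
  fibre_g: [0.7, 1.4, 2.1, 2.8, 3.5]
  protein_g: [1.6, 3.2, 4.8, 6.4, 8.0]
  fvn_pct: [40, 60, 80]
fvn_point_map: [0, 1, 2, 5]
# Protein gate: protein points only count if A-total < 11 or FVN points = 5.
protein_gate_a_total: 11
protein_gate_fvn_points: 5
# Classification thresholds ("less-healthy" at or above).
food_threshold: 4
beverage_threshold: 1
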