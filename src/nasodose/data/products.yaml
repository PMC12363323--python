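# Commercial nasal spray products: log-normal droplet mass distribution
# (mass median diameter x50, geometric standard deviation sigma_g), mean
# formulation mass per pump, and API concentration per mg of formulation.
- name: Flonase
  x50_um: 37.16
  sigma_g: 2.080
  shot_mass_mg: 104.51
  api_mcg_per_mg: 0.5     # 50 mcg per 100 mg formulation
- name: Nasacort
  x50_um: 43.81
  sigma_g: 1.994
  shot_mass_mg: 97.64
  api_mcg_per_mg: 0.5     # 55 mcg per 110 mg formulation
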