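# Example end-to-end run: simulate IU and CU deposition curves in the
# idealized airway at 15 L/min, then weight them by the built-in spray
# products. Reduce spray.n_droplets for a quick look.
mode: simulate
flow:
  rate_lpm: 15.0
spray:
  n_droplets: 3000
analysis:
  cutoff: 0.02
  products: [Flonase, Nasacort]
  project_to_lpm: 30.0
sensitivity:
  enabled: false
seeds:
  base: 42
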