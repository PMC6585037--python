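# End-to-end pipeline config for the packaged TOY-B network.
# Generate the model first:  coupledesign make-fixtures --out examples/fixtures
model: fixtures/TOY_B.xml
ids:
  product: R_p
  substrate: R_s
  biomass: R_bio
  atpm: R_m
environment:
  R_s: [0.0, 10.0]
formulations:
  MCSw:
    eps: 1.0e-4
    F: 0.1
    max_size: 2
  EAm:
    max_evaluations: 2000
    population_size: 30
    archive_size: 30
    runs: 3
filter:
  min_growth_fraction: 0.01
  coupling_fraction: 0.90
output_dir: results
seed: 1
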