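# coupledesign

Constraint-based strain design toolkit for growth-coupled product
synthesis.  Two routes produce reaction-knockout strategies:

* **Constrained minimal cut set (cMCS) enumeration** — target ("undesired")
  flux spaces are built as linear inequality systems in one of three
  formulations (`MCSe`, `MCSf`, `MCSw`); a dual system is assembled whose
  minimum-support solutions map to cut sets, enumerated k-shortest by MILP
  and constrained against a desired space (environment plus a biomass
  demand that discards lethal designs).
* **Multi-objective evolutionary search (SPEA2)** — knockout sets evolved
  under two fitness schemes: `EAw` (max growth, max production at
  max growth) and `EAm` (max growth, max of the FVA-minimum production at
  max growth, with a production-at-half-max acceptance test).

Strategies from either route flow through a shared three-criteria filter
(environmental feasibility, ≥1% of wild-type growth, non-zero production
at 90% of the mutant's maximum growth) and an analysis layer computing
production robustness, BPCY, carbon yield, pathway-usage distributions and
knockout frequencies from parsimonious-FBA phenotypes.

All linear and mixed-integer programs run on scipy's bundled HiGHS
solver; SBML (Level 3 + FBC) I/O is handled through COBRApy/libsbml.

## Layout

| module | contents |
| --- | --- |
| `model_core` | model representation, SBML I/O, reversible splitting, knockouts, environments |
| `phenotype_sim` | FBA / pFBA / FVA and the strong/weak coupling classifier |
| `intervention` | target and desired flux spaces, origin-point validation |
| `mcs_enum` | dual system, k-shortest MILP enumeration, minimality, desired-space constraining |
| `ea_design` | SPEA2 search with the `EAw`/`EAm` fitness schemes |
| `screen_analyze` | filtering pipeline and all strategy analytics |
| `fixtures_oracle` | toy networks, seeded random networks, brute-force oracles |
| `workbench_cli` | YAML-driven pipeline and the `coupledesign` CLI |

## CLI

```bash
# write the packaged toy networks as SBML
coupledesign make-fixtures --out fixtures/

# full pipeline from a config
coupledesign run --config examples/toy_b.yaml

# individual stages
coupledesign enumerate-mcs --model fixtures/TOY_B.xml --config cfg.yaml \
    --formulation MCSw --max-size 3 --out cutsets.tsv
coupledesign ea-optimize --model fixtures/TOY_B.xml --config cfg.yaml \
    --formulation EAm --runs 10 --seed 1 --out strategies.tsv
coupledesign filter --model fixtures/TOY_B.xml --strategies strategies.tsv \
    --config cfg.yaml --out filtered.tsv
coupledesign analyze --model fixtures/TOY_B.xml --strategies filtered.tsv \
    --config cfg.yaml --out-dir analysis/
```

A config looks like:

```yaml
model: TOY_B.xml
ids: {product: R_p, substrate: R_s, biomass: R_bio, atpm: R_m}
environment:
  R_s: [0.0, 10.0]
formulations:
  MCSw: {eps: 1.0e-4, F: 0.1, max_size: 3}
  EAm: {max_evaluations: 100000, runs: 10}
filter: {min_growth_fraction: 0.01, coupling_fraction: 0.90}
output_dir: results
seed: 1
```

Strategy files share one TSV schema across both optimization routes
(`reactions` semicolon-joined, `size`, `minimal`, `constrained`,
`formulation`).

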