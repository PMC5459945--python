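# orthodesign

Orthogonality-based metabolic strain design: quantify how separable
chemical production is from growth in a stoichiometric network, and find
branched "valve" designs that switch a cell between a growth phase and a
production phase.

Metabolic engineers usually *couple* product formation to growth. The
alternative pursued here is the opposite: make production **orthogonal** to
growth — share as few reactions as possible between the biomass-forming and
product-forming parts of the network — and control the biomass branch with
a single **metabolic valve** reaction. `orthodesign` provides the analysis
stack for that strategy:

* **Orthogonality score.** Enumerate elementary flux modes (EFMs), split
  them into biomass-only modes S_x (n of them) and product-only modes S_t
  (m of them), and score the network

      s(t, x) = |supp(t) ∩ supp(x)| / |supp(x)|
      OS = 1 − (1/(m·n)) Σ_{t∈S_t} Σ_{x∈S_x} s(t, x)

  OS = 1 means production is a pure biotransformation; OS = 0 means it runs
  entirely through the growth network. Multimodal pair distributions are
  detected with the bimodality coefficient (threshold 5/9) and scored at
  the dominant density mode instead of the mean. With no biomass-only
  modes (strong growth coupling) the score is undefined, by design.
* **ValveFind.** Enumerate minimal cut sets that eliminate every mode below
  a product-yield threshold (default 1 mol/mol), then search each cut set
  for a valve: one member whose restoration brings FBA growth back above
  90% of wild type. Designs are audited valve-off (growth 0, yield
  guaranteed, precursor synthesizability counted) and ranked by the
  orthogonality score of the valve-on reduced network.
* **Production envelopes.** Throttle the valve to 100/50/20/10/5% of its
  wild-type flux and trace the (biomass, product) envelope at each opening.
* **Protein cost.** Max–min driving force feasibility plus minimization of
  pathway protein cost M/(kcat·η_sat·η_therm) over metabolite
  concentrations, with kinetic/thermodynamic/saturation decomposition.

Models come from a documented JSON dialect (`docs/json_dialect.md`) or SBML
Level 3 + FBC with a YAML role sidecar. Six built-in toy networks make
every feature testable without downloads.

## Worked example

The normative fixture `branched_toy` converts substrate A into biomass
through A→B→{C,D}→E and into the target through a disjoint branch A→P:

```sh
$ orthodesign fixtures --name branched_toy --out toy.json
branched_toy: 6 metabolites, 9 reactions -> toy.json

$ orthodesign score --model toy.json --out score.tsv
INFO enumerated 3 elementary modes
INFO partition: m=1 product-only, n=2 biomass-only
score 0.8  (m=1, n=2) -> score.tsv
```

Three EFMs exist: two biomass-only ({R_up,v1,v2,v4,v_bio},
{R_up,v1,v3,v5,v_bio}) and one product-only ({R_up,v7,v8}). Each pair
shares only the uptake reaction, 1 of the 5 reactions of either biomass
mode, so AS = 0.2 and OS = 0.8 — a highly orthogonal network. Adding a
redundant shortcut v9: A→C (`branched_toy_redundant`) creates a fourth
mode and drops the score to 0.7833: redundancy shared between branches
costs orthogonality.

```sh
$ orthodesign valvefind --model toy.json --max-cuts 3 --out designs.tsv
INFO yield threshold 1 mol/mol, growth fraction 0.9, max cardinality 3
INFO 5 minimal cut sets up to cardinality 3
5 valve design(s) -> designs.tsv

$ cat designs.tsv
cutset  valve  restored_growth_fraction  score  precursors_off  product_yield_off
v1      v1     1                         0.8    0               1
v2,v3   v2     1                         0.8    0               1
v2,v5   v2     1                         0.8    0               1
v3,v4   v3     1                         0.8    0               1
v4,v5   v4     1                         0.8    0               1
```

The top design deletes nothing permanently: v1 alone is both the cut set
and the valve. Closing it drives growth to zero while the product yield
stays at 1 mol/mol; opening it restores 100% of wild-type growth. The
`envelope` subcommand shows the same valve throttled through
100→5% openings, and `cost` prices a pathway's enzymes from kcat/Km/ΔG′°
tables.

Every TSV is written with a JSON twin, and identical inputs produce
byte-identical outputs.

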