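# Model JSON dialect

A self-contained plain-text serialization of a stoichiometric model. Field
names mirror the in-memory types; coefficients are exact rationals (integers
or `"num/den"` strings), so a write→load→write cycle is byte-identical.

```json
{
  "name": "branched_toy",
  "metabolites": [
    {"id": "A", "name": "", "compartment": "c",
     "is_external": false, "is_precursor": false}
  ],
  "reactions": [
    {"id": "v1",
     "stoichiometry": {"A": -1, "B": 1},
     "reversible": false,
     "lower_bound": 0.0,
     "upper_bound": 1000.0,
     "role": "internal",
     "deletable": true}
  ]
}
```

Notes

* `role` is one of `internal`, `uptake`, `exchange`, `biomass`, `target`.
  Exactly one `uptake`, one `biomass` and one `target` reaction must be
  designated before running an analysis (either in the file or via
  `retag_roles` / the CLI `--uptake/--biomass/--target` flags).
* `deletable` may be omitted; it then defaults to `false` for the
  uptake/exchange/biomass/target roles and `true` otherwise.
* Stoichiometric coefficients may be given as JSON numbers (read exactly as
  their decimal literal, e.g. `0.1` becomes 1/10) or as rational strings
  like `"2/3"`.
* External metabolites (`is_external: true`) are not balanced; they may
  appear in stoichiometries but contribute no row to S.

SBML Level 3 + FBC input is also supported (`load_model(..., format="sbml")`).
Because SBML has no role semantics, a YAML sidecar supplies them:

```yaml
substrate_uptake: EX_glc__D_e
biomass_reaction: BIOMASS_Ecoli_core_w_GAM   # optional if an FBC objective exists
target_reaction: EX_succ_e
precursors: [g6p_c, f6p_c, r5p_c, e4p_c, g3p_c, 3pg_c, pep_c, pyr_c,
             accoa_c, akg_c, succoa_c, oaa_c]
non_deletable: [ATPM]
```
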