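# Native JSON model dialect

The canonical on-disk model format is a single UTF-8 JSON object.  It is
what `read_model`/`write_model` use by default, and serialization is
canonical (sorted keys, two-space indentation, trailing newline), so two
equal models always produce byte-identical files.

## Top-level keys

| key | type | meaning |
| --- | --- | --- |
| `name` | string | free-text model name |
| `objective` | string | reaction id optimized by default (may be empty) |
| `genes` | list of strings | all gene ids; derived from GPRs when absent |
| `metabolites` | list of objects | see below |
| `reactions` | list of objects | see below |

## Metabolite object

| key | type | notes |
| --- | --- | --- |
| `id` | string | unique; compartment as a square-bracket suffix, e.g. `crn[c]`, `crn[m]`; the part before the bracket is the compartment-free `base_id` |
| `name` | string | optional display name |

## Reaction object

| key | type | notes |
| --- | --- | --- |
| `id` | string | unique |
| `stoichiometry` | object | metabolite id → signed coefficient; negative = consumed, positive = produced; at least one nonzero entry |
| `lower_bound` / `upper_bound` | number | flux bounds (mmol gDW⁻¹ h⁻¹ by convention); default ±1000 when absent; `lower_bound ≤ upper_bound` |
| `gpr` | string | boolean gene rule with `and` / `or` / parentheses; empty = no gene association |
| `subsystem` | string | pathway label (e.g. `"Carnitine shuttle"`); empty allowed |
| `name` | string | optional display name |

## Conventions

- A reaction with exactly one nonzero stoichiometric entry is an exchange
  (boundary) reaction.  Exchanges are written as consumption of the
  metabolite (`{met: -1}`): positive flux is secretion, negative flux is
  uptake, and opening uptake means lowering `lower_bound`.
- Validation rejects duplicate ids, bounds with `lower_bound >
  upper_bound`, reactions referencing unknown metabolites, and GPRs
  referencing genes absent from `genes`.

## Example

```json
{
  "name": "chain",
  "objective": "DM_B",
  "genes": ["g1"],
  "metabolites": [{"id": "A[c]", "name": ""}, {"id": "B[c]", "name": ""}],
  "reactions": [
    {"id": "EX_A", "name": "", "stoichiometry": {"A[c]": -1.0},
     "lower_bound": -1.0, "upper_bound": 0.0, "gpr": "", "subsystem": ""},
    {"id": "A2B", "name": "", "stoichiometry": {"A[c]": -1.0, "B[c]": 1.0},
     "lower_bound": 0.0, "upper_bound": 1000.0, "gpr": "g1", "subsystem": ""},
    {"id": "DM_B", "name": "", "stoichiometry": {"B[c]": -1.0},
     "lower_bound": 0.0, "upper_bound": 1000.0, "gpr": "", "subsystem": ""}
  ]
}
```

SBML Level-3 files with the `fbc` package (flux-bound parameters and
gene-product associations) can be read and written through
`read_model(path, "sbml-subset")` / `write_model(model, path,
"sbml-subset")`; unknown SBML constructs are ignored with a logged warning
and only the native dialect round-trips bit-exactly.
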