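# Methods

This note documents the models and procedures fluxmark implements, the
assumptions baked into them, the tunable parameters, what the synthetic
data generator does and does not emulate, and the numerical and design
choices a maintainer should know about.

## Constraint-based core

A model is (S, lb, ub, GPR, subsystems): S is the m × n stoichiometric
matrix (negative = consumed, positive = produced), bounds are in
mmol gDW⁻¹ h⁻¹, and exchange reactions are exactly the single-entry
columns, written as `{met: -1}` so that negative flux is uptake. FBA and
FVA are solved with scipy's HiGHS simplex. FVA holds the objective at
`objective_fraction · opt` (default 1.0: the flux ranges *required for
optimal ATP production*, not a relaxation; exposed as a config knob). Only
objective values and FVA interval endpoints are contractual — flux vectors
at degenerate optima depend on the solver's vertex choice and are never
asserted.

Mass conservation, bound feasibility, blocked-reaction detection and
interval comparisons share one absolute tolerance, `TOLERANCE = 1e-6`.

`prune_blocked` removes reactions whose attainable flux interval lies in
[−tol, tol] with **every exchange opened to ±1000 and no objective
imposed** — pure stoichiometric/bound consistency, the standard
consistency-extraction convention. Removal iterates to a fixpoint and
unreferenced metabolites are dropped; surviving reactions keep their
original bounds. Two consequences worth knowing: an exchange whose only
internal partner is blocked is itself blocked (its net flux must be zero),
and removing a reaction can cascade — in the toy network, silencing the
transketolase-like bypass makes the phosphate exchange stoichiometrically
dead (it is the only reaction breaking the phosphate-moiety conservation),
so the High-dose model loses `TKT`, `EX_pi_e` and `PIt` together.

FVA monotonicity (relaxing a bound never shrinks an interval) holds at a
fixed objective floor. When `objective_fraction < 1` is combined with a
bound relaxation that *raises the optimum*, the floor rises too and
intervals can legitimately shrink; the property test pins the objective to
avoid asserting a false general claim.

## Physiology

* `biomass_fractions`: component masses are g per gDW, so fractions equal
  the masses and the remainder pool (default name `organic_acid`) closes
  the sum to exactly 1.
* `growth_rate_from_lengths`: per-interval length increments ΔLᵢ and rates
  ΔLᵢ/Δtᵢ are accumulated; cumulative ΔL (y, mm) is regressed on
  cumulative rate (x, mm h⁻¹). The axes are fixed this way *by design* so
  the least-squares slope carries hours and its inverse carries h⁻¹; with
  a constant sampling interval Δt the slope is exactly Δt. The Spearman
  rho/p of the plotted pair is returned alongside.
* `allometric_ocr`: OCR = a·massᵇ; a and b are configuration inputs
  (literature values for the organism), the caller normalizes units to
  µmol O₂ gDW⁻¹ h⁻¹.
* `cost_of_growth`: COG = β·µ·φ where β is the least-squares slope of OCR
  on relative growth rate and φ converts O₂ to ATP. φ defaults to 5.0
  (effective P/O ≈ 2.5, i.e. ~5 ATP per O₂); it is a required, visible
  parameter, not a constant. The β·µ·φ form is this package's
  unit-consistent definition of "cost of growth from the OCR–RGR
  correlation"; alternatives (e.g. intercept-inclusive variants) would be
  configuration changes, not code changes.
* `apply_physiology` changes exactly three bounds: biomass lower bound µ
  (growth must proceed), O₂ exchange lower bound −OCR (uptake capacity;
  a lower bound, not an equality), ATP-maintenance lower bound COG.

Reference magnitudes from embryo-larval zebrafish work (growth rate
0.011 h⁻¹, OCR 52 µmol O₂ gDW⁻¹ h⁻¹, COG 209 µmol ATP gDW⁻¹ h⁻¹, biomass
fractions 0.47/0.40/0.05/0.05/0.03) are used in tests as arithmetic
checks of the constraint plumbing; reproducing them from raw data would
require the external datasets and is out of scope.

## Omics integration

Counts are log₂(n+1)-transformed. Each gene's profile is binarized across
samples by optimal step-function approximation: for every allowed
discontinuity count d = 1..n−2, a dynamic program finds the SSE-minimal
d-break step function of the sorted vector (ties resolved to the
lexicographically smallest break set); each scale contributes the midpoint
flanking its strongest discontinuity, scored as jump/(SSE + ε) with
ε = 1e-12 (ties to the smallest index); the final threshold is the lower
median of the candidates and values strictly above it are 1. An exhaustive
enumeration over all break sets (n ≤ 8) is the ground truth the
implementation is tested against. Constant profiles carry no scale
information and keep a flat state (1 if expressed at all, else 0) with a
logged notice — relevant for the zero-dispersion synthetic tables.

Replicate aggregation per condition defaults to majority with ties → 1
(non-penalizing for n = 2 designs); `any`/`all` are available. Silencing
nulls the bounds of reactions whose GPR evaluates to 0; reactions without
gene associations (transport, exchange, pools — roughly the non-enzymatic
backbone) are deliberately left open, since nulling them would close
boundary fluxes wholesale. Genes missing from a state map count as
expressed (with a warning): absence of evidence never closes a reaction.

Metabolomics: auto-scaled relative abundances z rescale reference AUCs
either as AUC·2ᶻ (`exp2`, the default — z read as a log2 shift) or
AUC·max(0, 1+z) (`multiplicative`, floored at zero). Scaled availabilities
cap exchange uptake at −κ·availability; κ defaults to 1.0 and is the
single knob converting abundance units into flux units. Bundle
construction per arm is: exchange scaling → GPR silencing → pruning, with
every changed bound and removed reaction recorded as provenance, and a
final solvability check of the ATP demand (failure points at κ and the
imposed constraints).

## Biomarker discovery

Range classification per shared reaction: `equivalent` if both endpoints
agree within tolerance (Jaccard forced to 1), `non_overlapping` if the
intervals are separated by more than the tolerance (Jaccard 0), otherwise
`overlapping` with Jaccard = intersection/union length; reactions present
in one arm only are `absent`. The default pairing compares each exposure
level's dose arm against its own control arm (one comparison per level);
cross-level pairing is available in the config.

The impacted set defaults to non_overlapping ∪ overlapping. Connectivity
merges compartments on the metabolite base id and counts distinct impacted
reactions containing the species; ties break lexicographically. The
default exclusion list is the classic currency set {h2o, h, pi, ppi, o2,
co2, na1, k} — CoA, ATP and NAD species are *not* excluded, because
CoA-containing intermediates are legitimate biomarker candidates; the list
is fully configurable. The subsystem matrix normalizes per category by
default (each category column sums to 1: how strongly a subsystem is
represented *within* a category); per-subsystem and raw-count modes exist
because the alternative reading is equally defensible.

The carbon-limited assay closes every exchange uptake except the substrate
(lower bound −amount) and opens the free set {O₂, H₂O, CO₂, H⁺, Pi} to
±1000. Positive lower bounds on internal reactions (growth, maintenance)
are released by default so the assay measures pure catabolic capability —
otherwise a biomass demand whose precursors include lipids would make
every glucose-only assay infeasible. Pool and biomass fluxes reported at
the ATP optimum are therefore typically 0 in the toy network: with ATP as
the sole objective, diverting carbon into pools is never optimal.

## The synthetic generator and what passing tests mean

`make_toy_network` is deterministic: 54 metabolites, 62 reactions, 31
genes across compartments [e]/[c]/[m]. Energetics are exact by
construction: 34 ATP per glucose (2 glycolytic + 2 TCA substrate-level +
30 oxidative from 12 NADH at P/O 2.5) and 104.5 ATP per palmitoleate
(8 acetyl units, 39 NADH, minus one activation ATP). Chemistry is
deliberately lumped: fatty-acid activation is folded into CPT-I (so no
cytosolic CoA pool exists and carnitine, not CoA, is the shuttle's
signature cofactor — mirroring the high carnitine multiplicity genome-
scale models show across their per-acyl-species shuttle reactions), FAD
counts as NAD, water and phosphate live in single pools, and β-oxidation
of each chain is one thiolase-labelled step. Protons are tracked only
where needed to keep the proton exchange alive.

`simulate_counts` draws negative-binomial counts with mean
library·baseline·2^lfc and variance mean + dispersion·mean²;
`simulate_metabolomics` draws log-normal reference AUCs and Gaussian-noised
z shifts. Dispersion 0 / z-noise 0 collapse both to their planted means.

The canonical ground-truth scenario raises fatty-acid availability in the
dosed arms (z = +2/+2.5/+3 across Low/Medium/High) and switches off
dispensable pentose-bypass genes at the higher doses. The design is
deliberate: at the ATP optimum every substrate uptake saturates its
availability bound, so raising fat availability re-pins the entire
CPT-I/translocase/CPT-II shuttle at a new point range — all twelve shuttle
reactions classify as non-overlapping and carnitine (12 impacted
reactions) outranks free CoA (11) and the adenylates (8). Fully silencing
shuttle transcripts instead would null their bounds, and pruning would
then delete them from the dose model, so the comparison could only report
them `absent` — a set-level signal (visible in the Venn analysis, where
the bypass genes play exactly that role) rather than a range-level one.
The scenario also fixes dispersion and z-noise to 0: the planted effects
*are* the study conditions; with per-gene noise the step-function
binarization of a no-signal gene is a coin flip per sample, and a
two-replicate majority can spuriously silence an essential reaction —
a real failure mode of binarization-based integration on shallow
replication, noted here as a limitation rather than papered over with a
lucky seed.

Passing the recovery tests therefore shows that the pipeline's plumbing —
binarization, GPR evaluation, bound scaling, pruning, FVA, classification,
ranking — composes correctly and recovers a planted signal under noise-free
study conditions at toy scale. It does not show robustness to biological
noise at n = 2, to genome-scale degeneracy (thousands of alternate
optima), or to real exposure data; those require the external datasets
this package does not ship.

## Problem sizes and runtimes

Chosen so the whole suite runs comfortably on one CPU: the toy network has
62 reactions; the LP oracle suite checks 100 random networks of ≤ 8
reactions against exhaustive vertex enumeration (every basis × bound
assignment); the binarization oracle enumerates all break sets for vectors
of length ≤ 8; structural invariants are fuzzed over ~1050 cases. A full
pipeline run (three exposure levels, both arms, pruning + FVA + assays) is
about 1600 small LPs and takes a few seconds; the acceptance script
finishes in well under a minute.

## Known limitations

* The LP layer is plain FBA/FVA: no parsimonious FBA, loopless FVA,
  thermodynamic constraints or MILP gap-filling.
* SBML support is a read/write subset (L3 + fbc bounds and gene-product
  associations, subsystems via notes); only the native JSON dialect
  round-trips bit-exactly.
* The deposited-model compartment scheme is unknown; the square-bracket
  suffix convention is this package's own.
* Statistical significance of category counts and enrichment p-values are
  deliberately out of scope; the only inferential utility is the Spearman
  rank correlation.
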