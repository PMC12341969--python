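"""Transcript binarization with a step-function (BASC-A style) threshold.

Simulates a count table in which the pentose-bypass gene pgd is switched off
in the dosed conditions, log2(n+1)-transforms it, binarizes each gene across
samples, and aggregates replicate states per condition.
"""

from fluxmark import (
    PerturbationScenario,
    basc_a_binarize,
    binarize_matrix,
    gene_condition_state,
    make_toy_network,
    simulate_counts,
)

scenario = PerturbationScenario(
    lfc={"Medium": {"pgd": -6.0}, "High": {"pgd": -6.0}}, dispersion=0.0
)
model = make_toy_network()
matrix = simulate_counts(model.genes, scenario)
print("count table:", matrix.counts.shape[0], "genes x",
      matrix.counts.shape[1], "samples")
print(matrix.counts.loc[["pgd", "cpt2"]].to_string())

binarized = binarize_matrix(matrix)
print("\nbinarized pgd states:", binarized.states.loc["pgd"].tolist(),
      f"(threshold {binarized.thresholds['pgd']:.2f} on the log2 scale)")

for condition in scenario.conditions:
    state = gene_condition_state(binarized, condition)["pgd"]
    print(f"  pgd in {condition}: {'expressed' if state else 'silenced'}")

values = [0.0, 0.1, 0.0, 9.8, 10.0, 10.1]
binary, threshold = basc_a_binarize(values)
print(f"\nstandalone vector {values} -> {binary.tolist()}, "
      f"threshold {threshold:.2f} (midpoint of the dominant gap)")
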