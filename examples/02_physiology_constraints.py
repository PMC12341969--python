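"""Deriving and imposing whole-organism physiological constraints.

Computes the biomass composition remainder, a growth rate from a body-length
time series (inverse slope of the cumulative-increment linearization), an
allometric oxygen consumption rate, and a cost of growth; then constrains
the toy base model with all three rates.
"""

from fluxmark import (
    PhysiologyParams,
    allometric_ocr,
    apply_physiology,
    biomass_fractions,
    cost_of_growth,
    growth_rate_from_lengths,
    make_toy_network,
)

fractions = biomass_fractions(
    {"protein": 0.40, "lipid": 0.05, "trace_ion": 0.05, "dna": 0.03}
)
print("biomass fractions (organic acids close the sum to 1):")
for name, value in sorted(fractions.items()):
    print(f"  {name}: {value:.2f}")

times = [0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0]  # h
lengths = [3.50, 4.40, 5.10, 5.65, 6.10, 6.45, 6.75]  # mm
mu, rho, p = growth_rate_from_lengths(times, lengths)
print(f"\ngrowth rate mu = {mu:.4f} 1/h "
      f"(Spearman rho {rho:.2f}, p {p:.3g} for the linearized pair)")

ocr = allometric_ocr(mass=16.0, a=100.0, b=0.75)
print(f"allometric OCR = {ocr:.0f} umol O2/gDW/h (a*mass^b)")

pairs = [(400.0 * rgr + 40.0, rgr) for rgr in (0.005, 0.008, 0.011, 0.014)]
cog = cost_of_growth(pairs, mu_target=mu, atp_per_o2=5.0)
print(f"cost of growth = {cog:.1f} umol ATP/gDW/h (slope * mu * phi)")

model = make_toy_network()
constrained = apply_physiology(
    model, PhysiologyParams(mu, ocr, cog), "BIOMASS", "EX_o2_e", "ATPM"
)
print("\nimposed bounds: biomass lb",
      round(constrained.reaction("BIOMASS").lower_bound, 6),
      "| O2 exchange lb", constrained.reaction("EX_o2_e").lower_bound,
      "| ATP maintenance lb", round(constrained.reaction("ATPM").lower_bound, 3))
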