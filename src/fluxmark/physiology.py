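"""Whole-organism physiological parameterization of a metabolic base model.

Four experimentally derived quantities constrain the base model:

* biomass composition — proportional macromolecular fractions per gDW, with
  the organic-acid pool defined as the remainder closing the sum to 1;
* growth rate ``mu`` (h^-1) — obtained by linearizing a body-length time
  series: plot cumulative length change (mm) against cumulative length
  increment per unit time (mm h^-1); the least-squares slope carries units
  of hours and its inverse is ``mu``;
* oxygen consumption rate OCR (umol O2 gDW^-1 h^-1) — from the allometric
  relationship ``OCR = a * mass**b``;
* cost of growth COG (umol ATP gDW^-1 h^-1) — from the least-squares slope
  ``beta`` of OCR on relative growth rate (RGR), as
  ``COG = beta * mu * phi`` with ``phi`` the ATP-per-O2 conversion.

``apply_physiology`` imposes them: biomass lower bound = ``mu``, O2 exchange
lower bound = ``-OCR`` (uptake), ATP-maintenance lower bound = COG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, Reaction
from .stats import spearman_rho

#: Default ATP regenerated per O2 consumed (phi); a config parameter, not a
#: universal constant — the oxidative-phosphorylation literature puts the
#: effective in vivo value near 5 ATP/O2 (P/O ~ 2.5).
DEFAULT_ATP_PER_O2 = 5.0

FRACTION_NAMES = ("protein", "lipid", "trace_ion", "dna", "organic_acid")


@dataclass
class BiomassComposition:
    """Proportional biomass fractions plus precursor amounts in umol/gDW."""

    fractions: dict[str, float]
    precursor_amounts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("biomass fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biomass fractions sum to {total!r}, expected 1")


@dataclass
class PhysiologyParams:
    """Growth rate (h^-1), OCR (umol O2/gDW/h), COG (umol ATP/gDW/h), phi."""

    growth_rate: float
    ocr: float
    cog: float
    atp_per_o2: float = DEFAULT_ATP_PER_O2

    def __post_init__(self):
        for name in ("growth_rate", "ocr", "cog", "atp_per_o2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def biomass_fractions(
    component_masses: dict[str, float], remainder_name: str = "organic_acid"
) -> dict[str, float]:
    """Proportional fractions per gDW; the remainder pool closes the sum to 1.

    ``component_masses`` maps fraction names to masses in g per gDW, so the
    named fractions equal the masses and the remainder is 1 minus their sum.
    """
    if any(mass < 0 for mass in component_masses.values()):
        raise ValueError("component masses must be non-negative")
    total = sum(component_masses.values())
    if total > 1.0 + 1e-12:
        raise ValueError(f"component masses sum to {total} g > 1 g per gDW")
    fractions = dict(component_masses)
    fractions[remainder_name] = 1.0 - min(total, 1.0)
    return fractions


def auc_to_micromol(
    auc_table: dict[str, float],
    fraction_mass: float,
    molecular_weights: dict[str, float],
) -> dict[str, float]:
    """Distribute a biomass fraction's mass over metabolites by AUC share.

    Metabolite j receives ``fraction_mass * AUC_j / sum(AUC)`` grams,
    converted to umol/gDW through its molecular weight (g/mol):
    ``10^6 * share / MW_j``.  The mass shares sum to ``fraction_mass``.
    """
    if not auc_table:
        raise ValueError("empty AUC table")
    if any(v < 0 for v in auc_table.values()):
        raise ValueError("AUC values must be non-negative")
    total_auc = sum(auc_table.values())
    if total_auc <= 0:
        raise ValueError("all AUC values are zero; cannot apportion mass")
    amounts = {}
    for met, auc in auc_table.items():
        mw = molecular_weights[met]
        if mw <= 0:
            raise ValueError(f"molecular weight for {met!r} must be positive")
        share = fraction_mass * auc / total_auc
        amounts[met] = 1e6 * share / mw
    return amounts


def build_biomass_reaction(
    composition: BiomassComposition,
    cog_coupling: float = 0.0,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass[c]",
    atp_ids: tuple[str, str, str, str] = ("atp[c]", "adp[c]", "pi[c]", "h2o[c]"),
) -> Reaction:
    """Assemble the growth pseudo-reaction from precursor amounts.

    Each precursor is consumed at its umol/gDW amount divided by 1000 (the
    model's mmol convention) per unit biomass produced.  ``cog_coupling``
    (umol ATP per gDW biomass) adds growth-associated ATP hydrolysis:
    atp + h2o -> adp + pi at ``cog_coupling / 1000`` mmol.
    """
    if not composition.precursor_amounts:
        raise ValueError("composition has no precursor amounts")
    stoich: dict[str, float] = {}
    for met, amount in composition.precursor_amounts.items():
        stoich[met] = stoich.get(met, 0.0) - amount / 1000.0
    if cog_coupling > 0:
        atp, adp, pi, h2o = atp_ids
        coeff = cog_coupling / 1000.0
        stoich[atp] = stoich.get(atp, 0.0) - coeff
        stoich[h2o] = stoich.get(h2o, 0.0) - coeff
        stoich[adp] = stoich.get(adp, 0.0) + coeff
        stoich[pi] = stoich.get(pi, 0.0) + coeff
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass",
        name="biomass generation",
    )


def check_biomass_precursors(model: MetabolicModel, reaction: Reaction) -> None:
    """Raise with the missing ids if a biomass precursor is absent from the model."""
    known = set(model.metabolite_ids)
    missing = sorted(set(reaction.stoichiometry) - known)
    if missing:
        raise ValueError(f"biomass precursors absent from model: {missing}")


def growth_rate_from_lengths(times, lengths) -> tuple[float, float, float]:
    """Growth rate from a body-length time series, via the cumulative-increment
    linearization.

    Per-interval increments ``dL_i`` and rates ``dL_i/dt_i`` are accumulated;
    cumulative dL (y, mm) is regressed on cumulative rate (x, mm/h) by least
    squares.  The slope carries hours, and ``mu = 1/slope`` (h^-1).  Returns
    ``(mu, rho, p)`` with the Spearman correlation of the plotted pair.
    """
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if times.size != lengths.size:
        raise ValueError("times and lengths must have equal length")
    if times.size < 4:
        raise ValueError("need at least 4 time points")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("time points must be strictly increasing")
    increments = np.diff(lengths)
    rates = increments / dt
    x = np.cumsum(rates)
    y = np.cumsum(increments)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate series: cumulative rate has no variation")
    slope = float(np.polyfit(x, y, 1)[0])
    if slope <= 0:
        raise ValueError(f"non-positive linearization slope ({slope}); "
                         "series inconsistent with growth")
    rho, p = spearman_rho(x, y)
    return 1.0 / slope, rho, p


def allometric_ocr(mass: float, a: float, b: float) -> float:
    """Allometric metabolic rate ``OCR = a * mass**b``.

    ``a`` and ``b`` come from the literature for the organism at hand; the
    caller is responsible for normalizing units to umol O2 gDW^-1 h^-1.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if a <= 0:
        raise ValueError("allometric coefficient a must be positive")
    return a * mass**b


def cost_of_growth(
    ocr_rgr_pairs,
    mu_target: float,
    atp_per_o2: float = DEFAULT_ATP_PER_O2,
) -> float:
    """COG = beta * mu * phi, with beta the least-squares slope of OCR on RGR."""
    pairs = np.asarray(ocr_rgr_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (OCR, RGR) pairs")
    ocr_values, rgr_values = pairs[:, 0], pairs[:, 1]
    if np.allclose(rgr_values, rgr_values[0]):
        raise ValueError("degenerate RGR variance; slope undefined")
    beta = float(np.polyfit(rgr_values, ocr_values, 1)[0])
    return beta * mu_target * atp_per_o2


def apply_physiology(
    model: MetabolicModel,
    params: PhysiologyParams,
    biomass_rxn: str,
    o2_exchange: str,
    atp_maintenance: str,
) -> MetabolicModel:
    """Impose mu / OCR / COG as bounds on a copy of the model.

    biomass lower bound = mu; O2 exchange lower bound = -OCR (uptake
    capacity); ATP-maintenance lower bound = COG.  Exactly three bounds
    change; everything else is untouched.
    """
    constrained = model.copy()
    for rid in (biomass_rxn, o2_exchange, atp_maintenance):
        if not constrained.has_reaction(rid):
            raise KeyError(f"reaction {rid!r} not in model")
    constrained.reaction(biomass_rxn).lower_bound = params.growth_rate
    constrained.reaction(o2_exchange).lower_bound = -params.ocr
    constrained.reaction(atp_maintenance).lower_bound = params.cog
    return constrained
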