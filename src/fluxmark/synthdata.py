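"""Synthetic inputs with planted ground truth for every pipeline stage.

:func:`make_toy_network` builds a deterministic ~60-reaction whole-organism
toy model: glucose uptake and lumped glycolysis, an optional
pentose-phosphate bypass, pyruvate dehydrogenase plus a lumped TCA cycle,
oxidative phosphorylation at P/O 2.5, an ATP-maintenance demand (the
objective), four fatty-acyl species that enter mitochondria through a shared
carnitine shuttle (CPT-I with lumped activation, the translocase, CPT-II)
before a lumped 3-ketoacyl-CoA thiolase (BOXD) step, fatty-acid and acyl-CoA
biomass pool pseudo-reactions, and a biomass reaction assembled from a
biomass composition.  Chemistry is deliberately coarse: FAD counts as NAD,
phosphate and water live in single pools, and activation is folded into
CPT-I so that carnitine — not free CoA — is the shuttle's signature
cofactor, mirroring the high carnitine multiplicity genome-scale models
exhibit across their acyl-carnitine reactions.

:func:`simulate_counts` and :func:`simulate_metabolomics` emulate the
omics inputs (negative-binomial counts with per-condition log2 fold
changes; log-normal reference AUCs with auto-scaled z shifts), and
:func:`ground_truth_scenario` plants the canonical perturbation: dosed
arms see progressively raised fatty-acid availability (re-pinning every
carnitine-shuttle flux away from its control range) while dispensable
bypass genes are switched off at higher doses (exercising GPR silencing,
pruning and the reaction-set Venn analysis).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .gpr import gpr_genes
from .model import MetabolicModel, Metabolite, Reaction, validate
from .omics import ExpressionMatrix
from .physiology import BiomassComposition, biomass_fractions, build_biomass_reaction

#: Acyl species and their acetyl-CoA yield (chain length / 2, rounded).
FATTY_ACIDS = {"hdcea": 8, "hdca": 8, "ocdcea": 9, "ttdca": 7}

#: Default per-gDW biomass component masses (g) for the toy organism; the
#: organic-acid pool is the remainder fraction.
DEFAULT_COMPONENT_MASSES = {
    "protein": 0.40,
    "lipid": 0.05,
    "trace_ion": 0.05,
    "dna": 0.03,
}


@dataclass
class ToyNetworkSpec:
    """Motif toggles for the toy network; defaults give the full network."""

    glycolysis: bool = True
    tca: bool = True
    etc_atp: bool = True
    carnitine_shuttle: bool = True
    beta_oxidation: bool = True
    pentose_bypass: bool = True
    pools: bool = True
    biomass: bool = True
    fatty_acids: tuple[str, ...] = tuple(FATTY_ACIDS)
    glucose_uptake: float = 1.0
    fatty_acid_uptake: float = 0.5
    seed: int = 0


@dataclass
class PerturbationScenario:
    """Treatment design: per-condition gene fold-changes and metabolite z."""

    conditions: tuple[str, ...] = ("DMSO", "Low", "Medium", "High")
    control: str = "DMSO"
    replicates: int = 2
    lfc: dict = field(default_factory=dict)  # condition -> {gene: log2 fc}
    z: dict = field(default_factory=dict)  # condition -> {metabolite: z}
    baseline_count: float = 500.0
    baselines: dict = field(default_factory=dict)  # per-gene overrides
    dispersion: float = 0.1
    library_sizes: dict = field(default_factory=dict)  # sample -> factor
    z_noise_sd: float = 0.1
    auc_baselines: dict = field(default_factory=dict)
    auc_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.control not in self.conditions:
            raise ValueError(f"control {self.control!r} not among conditions")
        for table in (self.lfc, self.z):
            effects = table.get(self.control, {})
            if any(v != 0 for v in effects.values()):
                raise ValueError("control condition must have all effects 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PerturbationScenario":
        data = dict(data)
        data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PerturbationScenario":
        return cls.from_dict(json.loads(text))


def _exchange(rid, met, lb, ub=1000.0, name=""):
    return Reaction(
        id=rid, stoichiometry={met: -1.0}, lower_bound=lb, upper_bound=ub,
        subsystem="Exchange", name=name,
    )


def make_toy_network(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Deterministic toy metabolic model with planted subsystem structure."""
    spec = spec or ToyNetworkSpec()
    if not (spec.glycolysis and spec.tca and spec.etc_atp):
        raise ValueError(
            "glycolysis, tca and etc_atp are core motifs; disabling them "
            "leaves no ATP-feasible network"
        )
    mets: list[str] = []
    rxns: list[Reaction] = []

    def M(met_id):
        if met_id not in mets:
            mets.append(met_id)
        return met_id

    def R(rid, stoich, lb, ub, subsystem, gpr="", name=""):
        for met_id in stoich:
            M(met_id)
        rxns.append(Reaction(
            id=rid, stoichiometry=dict(stoich), lower_bound=lb, upper_bound=ub,
            gpr=gpr, subsystem=subsystem, name=name,
        ))

    B = 1000.0

    # exchanges
    rxns.append(_exchange("EX_glc__D_e", M("glc__D[e]"), -spec.glucose_uptake,
                          name="glucose exchange"))
    for fa in spec.fatty_acids:
        rxns.append(_exchange(f"EX_{fa}_e", M(f"{fa}[e]"), -spec.fatty_acid_uptake,
                              name=f"{fa} exchange"))
    for met, rid in (("o2", "EX_o2_e"), ("co2", "EX_co2_e"), ("h2o", "EX_h2o_e"),
                     ("h", "EX_h_e"), ("pi", "EX_pi_e")):
        rxns.append(_exchange(rid, M(f"{met}[e]"), -B))

    # transport
    R("GLCt", {"glc__D[e]": -1, "glc__D[c]": 1}, 0, B, "Transport", gpr="slc2a1")
    for fa in spec.fatty_acids:
        R(f"FAt_{fa}", {f"{fa}[e]": -1, f"{fa}[c]": 1}, 0, B, "Transport",
          gpr="slc27a1")
    R("O2t", {"o2[e]": -1, "o2[m]": 1}, -B, B, "Transport")
    R("CO2t", {"co2[m]": -1, "co2[e]": 1}, -B, B, "Transport")
    R("H2Ot", {"h2o[e]": -1, "h2o[c]": 1}, -B, B, "Transport")
    R("Ht", {"h[c]": -1, "h[e]": 1}, -B, B, "Transport")
    R("PIt", {"pi[e]": -1, "pi[c]": 1}, -B, B, "Transport")
    R("PYRtm", {"pyr[c]": -1, "pyr[m]": 1}, 0, B, "Transport", gpr="mpc1 and mpc2")
    R("ATPtm", {"atp[m]": -1, "adp[c]": -1, "atp[c]": 1, "adp[m]": 1}, 0, B,
      "Transport", gpr="slc25a4", name="adenine nucleotide translocase")
    R("NADHtm", {"nadh[c]": -1, "nad[m]": -1, "nad[c]": 1, "nadh[m]": 1}, 0, B,
      "Transport", gpr="got1 and got2", name="redox shuttle")

    # glycolysis (lumped to three steps; net 2 ATP + 2 NADH per glucose)
    R("HEX1", {"glc__D[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1, "h[c]": 1},
      0, B, "Glycolysis", gpr="hk1")
    R("PFK", {"g6p[c]": -1, "atp[c]": -1, "g3p[c]": 2, "adp[c]": 1},
      0, B, "Glycolysis", gpr="pfkma or pfkmb")
    R("GLYC2", {"g3p[c]": -1, "nad[c]": -1, "adp[c]": -2, "pi[c]": -1,
                "pyr[c]": 1, "nadh[c]": 1, "atp[c]": 2, "h2o[c]": 1},
      0, B, "Glycolysis", gpr="gapdh and pkma",
      name="lower glycolysis (GAPDH..PK lump)")

    # dispensable pentose-phosphate-style bypasses (ATP-suboptimal by design)
    if spec.pentose_bypass:
        R("GND", {"g6p[c]": -1, "nad[c]": -1, "g3p[c]": 1, "co2[m]": 1,
                  "nadh[c]": 1},
          0, B, "Pentose phosphate pathway", gpr="pgd")
        R("TKT", {"g6p[c]": -2, "g3p[c]": 3}, 0, B,
          "Pentose phosphate pathway", gpr="tkt")

    # TCA (PDH + three lumped spans; FAD counted as NAD)
    R("PDH", {"pyr[m]": -1, "coa[m]": -1, "nad[m]": -1,
              "accoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
      0, B, "TCA cycle", gpr="pdha1 and pdhb", name="pyruvate dehydrogenase")
    R("CS", {"accoa[m]": -1, "oaa[m]": -1, "h2o[c]": -1, "nad[m]": -1,
             "akg[m]": 1, "coa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
      0, B, "TCA cycle", gpr="cs and idh3a", name="citrate synthase..IDH lump")
    R("AKGDH", {"akg[m]": -1, "coa[m]": -1, "nad[m]": -1,
                "succoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
      0, B, "TCA cycle", gpr="ogdh and dlst", name="alpha-ketoglutarate dehydrogenase")
    R("SUCOAS", {"succoa[m]": -1, "adp[m]": -1, "pi[c]": -1, "nad[m]": -2,
                 "h2o[c]": -1, "oaa[m]": 1, "atp[m]": 1, "coa[m]": 1,
                 "nadh[m]": 2},
      0, B, "TCA cycle", gpr="suclg1 and mdh2", name="SCS..MDH lump")

    # oxidative phosphorylation, P/O = 2.5
    R("ETC", {"nadh[m]": -2, "o2[m]": -1, "adp[m]": -5, "pi[c]": -5,
              "nad[m]": 2, "atp[m]": 5, "h2o[c]": 2},
      0, B, "Oxidative phosphorylation", gpr="mt-nd1 and mt-co1 and atp5fa1")

    # ATP maintenance demand — the model objective
    R("ATPM", {"atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1, "h[c]": 1},
      0, B, "ATP maintenance", name="ATP maintenance (renewal)")

    # carnitine shuttle (activation lumped into CPT-I) + beta-oxidation
    if spec.carnitine_shuttle:
        for fa in spec.fatty_acids:
            R(f"CPT1_{fa}",
              {f"{fa}[c]": -1, "atp[c]": -1, "crn[c]": -1,
               f"{fa}crn[c]": 1, "adp[c]": 1, "pi[c]": 1},
              0, B, "Carnitine shuttle", gpr="cpt1a or cpt1b",
              name=f"CPT-I ({fa}, activation lumped)")
            R(f"CRNt_{fa}",
              {f"{fa}crn[c]": -1, "crn[m]": -1, f"{fa}crn[m]": 1, "crn[c]": 1},
              0, B, "Carnitine shuttle", gpr="slc25a20",
              name=f"carnitine-acylcarnitine translocase ({fa})")
            R(f"CPT2_{fa}",
              {f"{fa}crn[m]": -1, "coa[m]": -1, f"{fa}coa[m]": 1, "crn[m]": 1},
              0, B, "Carnitine shuttle", gpr="cpt2", name=f"CPT-II ({fa})")
    if spec.beta_oxidation:
        for fa in spec.fatty_acids:
            n_units = FATTY_ACIDS[fa]
            R(f"BOXD_{fa}",
              {f"{fa}coa[m]": -1, "coa[m]": -(n_units - 1),
               "nad[m]": -(n_units - 1), "h2o[c]": -(n_units - 1),
               "accoa[m]": n_units, "nadh[m]": n_units - 1},
              0, B, "Fatty acid oxidation", gpr="hadha and hadhb",
              name=f"3-ketoacyl-CoA thiolase lump ({fa})")

    # biomass precursor pools and the biomass reaction
    if spec.pools:
        for fa in spec.fatty_acids:
            R(f"FAPOOL_{fa}", {f"{fa}[c]": -1, "fapool[c]": 1}, 0, B,
              "Pool reactions", name=f"fatty acid pool ({fa})")
            R(f"ACOAPOOL_{fa}",
              {f"{fa}coa[m]": -1, "acoapool[c]": 1, "coa[m]": 1}, 0, B,
              "Pool reactions", name=f"acyl-CoA pool ({fa})")
        R("DM_fapool_c", {"fapool[c]": -1}, 0, B, "Pool reactions")
        R("DM_acoapool_c", {"acoapool[c]": -1}, 0, B, "Pool reactions")
    if spec.biomass:
        if not spec.pools:
            raise ValueError("biomass motif requires the pools motif")
        composition = BiomassComposition(
            fractions=biomass_fractions(DEFAULT_COMPONENT_MASSES),
            precursor_amounts={"pyr[c]": 500.0, "fapool[c]": 50.0,
                               "acoapool[c]": 20.0},
        )
        biomass_rxn = build_biomass_reaction(composition, cog_coupling=20000.0)
        for met_id in biomass_rxn.stoichiometry:
            M(met_id)
        rxns.append(biomass_rxn)
        rxns.append(_exchange("SK_biomass_c", M("biomass[c]"), 0.0,
                              name="biomass drain"))

    genes = sorted(set().union(*(gpr_genes(r.gpr) for r in rxns), set()))
    model = MetabolicModel(
        metabolites=[Metabolite(id=met_id) for met_id in mets],
        reactions=rxns,
        genes=genes,
        objective_id="ATPM",
        name=f"fluxmark-toy-{spec.seed}",
    )
    validate(model)
    from .lp import atp_yield_assay

    if atp_yield_assay(model, "ATPM") <= 0:
        raise ValueError("toy network spec yields no ATP; motif set infeasible")
    return model


def simulate_counts(
    genes, scenario: PerturbationScenario, seed: int | None = None
) -> ExpressionMatrix:
    """Negative-binomial transcript counts under the scenario's design.

    Mean for gene g in condition c is ``library_size * baseline_g *
    2**lfc[c][g]``; variance is ``mean + dispersion * mean**2``.  A
    dispersion of 0 collapses the count model to its (rounded) mean,
    making the table seed-independent.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    genes = list(genes)
    samples, conditions = [], {}
    for condition in scenario.conditions:
        for replicate in range(1, scenario.replicates + 1):
            sample = f"{condition}_{replicate}"
            samples.append(sample)
            conditions[sample] = condition
    data = np.zeros((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        condition = conditions[sample]
        lib = scenario.library_sizes.get(sample, 1.0)
        for i, gene in enumerate(genes):
            baseline = scenario.baselines.get(gene, scenario.baseline_count)
            lfc = scenario.lfc.get(condition, {}).get(gene, 0.0)
            mean = lib * baseline * 2.0**lfc
            if scenario.dispersion > 0:
                size = 1.0 / scenario.dispersion
                p = size / (size + mean)
                data[i, j] = rng.negative_binomial(size, p)
            else:
                data[i, j] = round(mean)
    counts = pd.DataFrame(data, index=genes, columns=samples)
    return ExpressionMatrix(counts=counts, condition_of=conditions)


def simulate_metabolomics(
    metabolites, scenario: PerturbationScenario, seed: int | None = None
) -> tuple[dict[str, float], pd.DataFrame]:
    """Log-normal reference AUCs and a metabolite x condition z table.

    z values equal the scenario's planted shifts plus Gaussian noise of
    standard deviation ``z_noise_sd`` (0 reproduces the plan exactly).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    metabolites = list(metabolites)
    reference = {}
    for met in metabolites:
        baseline = scenario.auc_baselines.get(met, 1.0)
        reference[met] = float(
            baseline * rng.lognormal(mean=0.0, sigma=scenario.auc_sigma)
        )
    z_table = pd.DataFrame(0.0, index=metabolites, columns=list(scenario.conditions))
    for condition in scenario.conditions:
        planted = scenario.z.get(condition, {})
        for met in metabolites:
            noise = rng.normal(0.0, scenario.z_noise_sd) if scenario.z_noise_sd > 0 else 0.0
            z_table.loc[met, condition] = planted.get(met, 0.0) + noise
    return reference, z_table


def ground_truth_scenario(seed: int = 0) -> PerturbationScenario:
    """The canonical planted perturbation used for end-to-end recovery.

    Dosed arms raise the availability of all four fatty-acyl species
    (z = +2/+2.5/+3 for Low/Medium/High), which re-pins every
    carnitine-shuttle flux at the new uptake level and must surface as
    non-overlapping shuttle ranges with carnitine the top-connectivity
    metabolite.  Medium and High additionally switch off the dispensable
    pentose-bypass genes (pgd, then pgd+tkt), so those reactions are
    silenced, pruned, and show up as set differences in the Venn analysis.
    Count dispersion and z noise are 0: the planted effects are the study
    conditions themselves, not draws around them.
    """
    fa_z = {"Low": 2.0, "Medium": 2.5, "High": 3.0}
    return PerturbationScenario(
        lfc={
            "Low": {},
            "Medium": {"pgd": -6.0},
            "High": {"pgd": -6.0, "tkt": -6.0},
        },
        z={level: {fa: shift for fa in FATTY_ACIDS} for level, shift in fa_z.items()},
        dispersion=0.0,
        z_noise_sd=0.0,
        auc_baselines={"glc__D": 1.0, "hdcea": 0.5, "hdca": 0.5, "ocdcea": 0.5,
                       "ttdca": 0.5, "crn": 0.3, "chsterol": 0.2},
        auc_sigma=0.2,
        seed=seed,
    )


#: Metabolites the synthetic metabolomics panel measures (includes two
#: species, carnitine and cholesterol, with no matching exchange — they
#: exercise the unmatched-metabolite path).
MEASURED_METABOLITES = ("glc__D", "hdcea", "hdca", "ocdcea", "ttdca", "crn", "chsterol")
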