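"""End-to-end orchestration: synthetic inputs -> physiology-constrained base
model -> condition-specific bundles -> FVA comparison -> biomarker report.

Every stage is an ordinary library call; this module only sequences them,
applies a validated :class:`PipelineConfig`, logs stage-scoped progress to
stderr, and writes machine-readable outputs plus a manifest with the seed,
config hash and a checksum for every artifact (rerunning with the same
config reproduces every byte; wall-clock time appears only in logs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    DEFAULT_EXCLUDED_METABOLITES,
    carbon_limited_assay,
    classify_ranges,
    metabolite_connectivity,
    subsystem_matrix,
    venn_reactions,
)
from .errors import PipelineError
from .lp import TOLERANCE, fva
from .model import model_to_json, write_model
from .omics import (
    binarize_matrix,
    build_condition_bundle,
    scale_metabolomics,
)
from .physiology import (
    PhysiologyParams,
    allometric_ocr,
    biomass_fractions,
    cost_of_growth,
    growth_rate_from_lengths,
)
from .synthdata import (
    DEFAULT_COMPONENT_MASSES,
    MEASURED_METABOLITES,
    PerturbationScenario,
    ToyNetworkSpec,
    ground_truth_scenario,
    make_toy_network,
    simulate_counts,
    simulate_metabolomics,
)

logger = logging.getLogger(__name__)

#: Synthetic body-length series (h, mm).  The sampling interval is constant
#: at 100 h, so the cumulative-increment linearization has slope exactly
#: 100 h and the recovered growth rate is 0.01 h^-1 by construction.
SYNTHETIC_LENGTH_SERIES = (
    (0.0, 3.50), (100.0, 4.40), (200.0, 5.10), (300.0, 5.65),
    (400.0, 6.10), (500.0, 6.45), (600.0, 6.75),
)

#: Synthetic (OCR, RGR) calibration pairs on the exact line OCR = 400*RGR + 40.
SYNTHETIC_OCR_RGR_PAIRS = tuple(
    (400.0 * rgr + 40.0, rgr) for rgr in (0.005, 0.008, 0.011, 0.014, 0.017, 0.020)
)


@dataclass
class PipelineConfig:
    """All pipeline tunables; validated on construction."""

    seed: int = 0
    kappa: float = 1.0  # availability -> uptake-bound scale
    atp_per_o2: float = 5.0  # phi
    allometry_a: float = 100.0
    allometry_b: float = 0.75
    body_mass: float = 16.0  # gDW, toy scale
    objective_fraction: float = 1.0
    tolerance: float = TOLERANCE
    aggregation_rule: str = "majority"
    scaling_mode: str = "exp2"
    comparison_pairing: str = "dose_vs_control"  # or "cross_level"
    subsystem_normalize: str = "by_category"
    impacted_categories: tuple[str, ...] = ("non_overlapping", "overlapping")
    excluded_metabolites: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDED_METABOLITES))
    levels: tuple[str, ...] = ("Low", "Medium", "High")
    biomass_rxn: str = "BIOMASS"
    o2_exchange: str = "EX_o2_e"
    atp_maintenance: str = "ATPM"
    objective_id: str = "ATPM"
    carbon_substrates: tuple[str, ...] = ("EX_glc__D_e", "EX_hdcea_e")
    carbon_report_ids: tuple[str, ...] = (
        "PDH", "AKGDH", "BOXD_hdcea", "DM_fapool_c", "DM_acoapool_c",
    )

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 < self.objective_fraction <= 1):
            raise ValueError("objective_fraction must be in (0, 1]")
        if self.aggregation_rule not in ("any", "all", "majority"):
            raise ValueError(f"unknown aggregation rule {self.aggregation_rule!r}")
        if self.scaling_mode not in ("exp2", "multiplicative"):
            raise ValueError(f"unknown scaling mode {self.scaling_mode!r}")
        if self.comparison_pairing not in ("dose_vs_control", "cross_level"):
            raise ValueError(f"unknown pairing {self.comparison_pairing!r}")
        unknown = set(self.impacted_categories) - {
            "non_overlapping", "overlapping", "equivalent"
        }
        if unknown:
            raise ValueError(f"unknown impacted categories: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        for key in ("impacted_categories", "excluded_metabolites", "levels",
                    "carbon_substrates", "carbon_report_ids"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()


@dataclass
class PipelineResult:
    """In-memory results of a full pipeline run."""

    config: PipelineConfig
    params: PhysiologyParams
    fractions: dict[str, float]
    base_model: object
    bundles: dict
    comparisons: dict
    subsystems: dict
    connectivity: dict
    venn: object
    carbon: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _stage(name):
    logger.info("[%s] starting", name)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    scenario: PerturbationScenario | None = None,
) -> PipelineResult:
    """Execute the full analysis and write a report directory.

    Stage order: synthetic inputs -> physiology -> omics transforms ->
    condition bundles -> FVA -> range comparison -> subsystem matrix ->
    connectivity ranking -> reaction Venn -> carbon-limited assays.
    Any stage failure aborts with the stage name and cause.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "models").mkdir(exist_ok=True)
    scenario = scenario or ground_truth_scenario(config.seed)

    stage = "simulate"
    try:
        _stage(stage)
        model = make_toy_network(ToyNetworkSpec(seed=config.seed))
        expression = simulate_counts(model.genes, scenario, seed=config.seed)
        reference_auc, z_table = simulate_metabolomics(
            MEASURED_METABOLITES, scenario, seed=config.seed
        )

        stage = "physiology"
        _stage(stage)
        times = [t for t, _ in SYNTHETIC_LENGTH_SERIES]
        lengths = [l for _, l in SYNTHETIC_LENGTH_SERIES]
        mu, rho, p_value = growth_rate_from_lengths(times, lengths)
        ocr = allometric_ocr(config.body_mass, config.allometry_a, config.allometry_b)
        cog = cost_of_growth(SYNTHETIC_OCR_RGR_PAIRS, mu, config.atp_per_o2)
        params = PhysiologyParams(
            growth_rate=mu, ocr=ocr, cog=cog, atp_per_o2=config.atp_per_o2
        )
        fractions = biomass_fractions(DEFAULT_COMPONENT_MASSES)
        from .physiology import apply_physiology

        base_model = apply_physiology(
            model, params, config.biomass_rxn, config.o2_exchange,
            config.atp_maintenance,
        )

        stage = "omics"
        _stage(stage)
        binarized = binarize_matrix(expression)
        availability = {
            condition: scale_metabolomics(
                reference_auc,
                z_table[condition].to_dict(),
                mode=config.scaling_mode,
                condition=condition,
            )
            for condition in scenario.conditions
        }

        stage = "bundles"
        _stage(stage)
        bundles = {}
        for level in config.levels:
            bundles[level] = build_condition_bundle(
                base_model,
                binarized,
                availability[scenario.control],
                availability[level],
                label=level,
                rule=config.aggregation_rule,
                kappa=config.kappa,
                objective_id=config.objective_id,
            )

        stage = "fva"
        _stage(stage)
        fva_results = {}
        for level, bundle in bundles.items():
            fva_results[level] = (
                fva(bundle.control_model, config.objective_id,
                    config.objective_fraction),
                fva(bundle.dose_model, config.objective_id,
                    config.objective_fraction),
            )

        stage = "compare"
        _stage(stage)
        comparisons, subsystems, connectivity = {}, {}, {}
        if config.comparison_pairing == "dose_vs_control":
            pairs = {
                level: (fva_results[level][0], fva_results[level][1],
                        bundles[level].control_model)
                for level in config.levels
            }
        else:  # cross_level: each level's dose arm against the first level's
            first = config.levels[0]
            pairs = {
                f"{level}_vs_{first}": (
                    fva_results[first][1], fva_results[level][1],
                    bundles[first].dose_model,
                )
                for level in config.levels[1:]
            }
        excluded = frozenset(config.excluded_metabolites)
        for key, (fva_control, fva_dose, reference_model) in pairs.items():
            comparison = classify_ranges(fva_control, fva_dose, config.tolerance)
            comparisons[key] = comparison
            subsystem_of = {
                r.id: r.subsystem for r in reference_model.reactions
            }
            subsystems[key] = subsystem_matrix(
                comparison, subsystem_of, normalize=config.subsystem_normalize
            )
            connectivity[key] = metabolite_connectivity(
                comparison,
                reference_model,
                impacted=config.impacted_categories,
                exclude=excluded,
            )

        stage = "venn"
        _stage(stage)
        venn = venn_reactions(
            {level: set(bundles[level].dose_model.reaction_ids)
             for level in config.levels}
        )

        stage = "carbon"
        _stage(stage)
        carbon_rows = []
        assay_models = {"Control": bundles[config.levels[0]].control_model}
        assay_models.update(
            {level: bundles[level].dose_model for level in config.levels}
        )
        for model_label, assay_model in assay_models.items():
            for substrate in config.carbon_substrates:
                report_ids = [
                    rid for rid in config.carbon_report_ids
                    if assay_model.has_reaction(rid)
                ]
                fluxes = carbon_limited_assay(
                    assay_model, substrate, amount=1.0,
                    objective_id=config.objective_id, report_ids=report_ids,
                )
                for rid, flux in fluxes.items():
                    carbon_rows.append(
                        {"model": model_label, "substrate": substrate,
                         "reaction": rid, "flux": flux}
                    )
        carbon = pd.DataFrame(carbon_rows)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "write"
    _stage(stage)
    result = PipelineResult(
        config=config, params=params, fractions=fractions, base_model=base_model,
        bundles=bundles, comparisons=comparisons, subsystems=subsystems,
        connectivity=connectivity, venn=venn, carbon=carbon,
    )
    _write_outputs(result, out_dir, expression, z_table, reference_auc)
    return result


def _float(x):
    return float(np.round(x, 10))


def _write_outputs(result, out_dir: Path, expression, z_table, reference_auc):
    config = result.config
    write_model(result.base_model, out_dir / "models" / "base.json")
    for level, bundle in result.bundles.items():
        write_model(bundle.control_model, out_dir / "models" / f"{level}_control.json")
        write_model(bundle.dose_model, out_dir / "models" / f"{level}_dose.json")
        pd.DataFrame({"constraint": bundle.provenance}).to_csv(
            out_dir / f"provenance_{level}.tsv", sep="\t", index=False
        )
    expression.counts.to_csv(out_dir / "counts.tsv", sep="\t")
    z_table.to_csv(out_dir / "metabolomics_z.tsv", sep="\t")
    pd.Series(reference_auc, name="reference_auc").to_csv(
        out_dir / "reference_auc.tsv", sep="\t"
    )

    for key, comparison in result.comparisons.items():
        rows = []
        for rid, entry in sorted(comparison.entries.items()):
            rows.append({
                "reaction": rid,
                "control_min": entry.control_range[0] if entry.control_range else "",
                "control_max": entry.control_range[1] if entry.control_range else "",
                "dose_min": entry.dose_range[0] if entry.dose_range else "",
                "dose_max": entry.dose_range[1] if entry.dose_range else "",
                "jaccard": _float(entry.jaccard),
                "category": entry.category,
            })
        pd.DataFrame(rows).to_csv(out_dir / f"comparison_{key}.tsv", sep="\t",
                                  index=False)
        result.subsystems[key].round(10).to_csv(
            out_dir / f"subsystems_{key}.tsv", sep="\t"
        )
        pd.DataFrame(
            result.connectivity[key].ranking, columns=["metabolite", "reactions"]
        ).to_csv(out_dir / f"connectivity_{key}.tsv", sep="\t", index=False)

    result.carbon.to_csv(out_dir / "carbon_assay.tsv", sep="\t", index=False)
    with open(out_dir / "venn.json", "w", encoding="utf-8") as handle:
        json.dump(result.venn.as_dict(), handle, indent=2, sort_keys=True)
    physiology = {
        "growth_rate_per_h": _float(result.params.growth_rate),
        "ocr_umol_o2_per_gdw_h": _float(result.params.ocr),
        "cog_umol_atp_per_gdw_h": _float(result.params.cog),
        "atp_per_o2": result.params.atp_per_o2,
        "biomass_fractions": {k: _float(v) for k, v in result.fractions.items()},
    }
    with open(out_dir / "physiology.json", "w", encoding="utf-8") as handle:
        json.dump(physiology, handle, indent=2, sort_keys=True)
    config.to_yaml(out_dir / "config.yaml")

    manifest = {
        "fluxmark_version": __version__,
        "seed": config.seed,
        "config_sha256": config.checksum(),
        "outputs": {},
    }
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["outputs"][str(path.relative_to(out_dir))] = digest
    manifest["base_model_sha256"] = hashlib.sha256(
        model_to_json(result.base_model).encode()
    ).hexdigest()
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    result.manifest = manifest


REQUIRED_ARTIFACTS = ("venn.json", "carbon_assay.tsv", "physiology.json",
                      "manifest.json")


def render_report(report_dir) -> str:
    """Markdown summary of a completed report directory.

    Includes the Venn table, the top-10 connectivity ranking, the subsystem
    matrix and the carbon-assay table; raises listing missing artifacts if
    the directory is incomplete.  Percentages print to one decimal place.
    """
    report_dir = Path(report_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (report_dir / a).exists()]
    if missing:
        raise PipelineError(f"incomplete report directory; missing: {missing}")

    lines = ["# fluxmark pipeline report", ""]
    with open(report_dir / "physiology.json", encoding="utf-8") as handle:
        physiology = json.load(handle)
    lines += ["## Physiological parameters", ""]
    for key in ("growth_rate_per_h", "ocr_umol_o2_per_gdw_h",
                "cog_umol_atp_per_gdw_h"):
        lines.append(f"- {key}: {physiology[key]}")
    fractions = physiology["biomass_fractions"]
    lines.append(
        "- biomass fractions: "
        + ", ".join(f"{k} {v:.2f}" for k, v in sorted(fractions.items()))
    )
    lines.append("")

    with open(report_dir / "venn.json", encoding="utf-8") as handle:
        venn = json.load(handle)
    lines += ["## Shared and unique reactions", "",
              "| region | reactions | % of union |", "| --- | --- | --- |"]
    for region, size in sorted(venn["regions"].items()):
        pct = venn["fractions_pct"][region]
        lines.append(f"| {region} | {size} | {pct:.1f} |")
    lines.append(f"\nUnion: {venn['union_size']} reactions; shared by all three: "
                 f"{venn['all_shared_size']}.")
    lines.append("")

    for connectivity_path in sorted(report_dir.glob("connectivity_*.tsv")):
        key = connectivity_path.stem.replace("connectivity_", "")
        table = pd.read_csv(connectivity_path, sep="\t")
        lines += [f"## Metabolite connectivity ({key})", ""]
        if table.empty:
            lines.append("no impacted reactions")
        else:
            lines += ["| rank | metabolite | impacted reactions |",
                      "| --- | --- | --- |"]
            for rank, row in enumerate(table.head(10).itertuples(index=False), 1):
                lines.append(f"| {rank} | {row.metabolite} | {row.reactions} |")
        lines.append("")

    for subsystem_path in sorted(report_dir.glob("subsystems_*.tsv")):
        key = subsystem_path.stem.replace("subsystems_", "")
        table = pd.read_csv(subsystem_path, sep="\t", index_col=0)
        lines += [f"## Subsystem representation ({key})", "",
                  "| subsystem | " + " | ".join(table.columns) + " |",
                  "| --- |" + " --- |" * len(table.columns)]
        for subsystem, row in table.iterrows():
            cells = " | ".join(f"{v:.3f}" for v in row)
            lines.append(f"| {subsystem} | {cells} |")
        lines.append("")

    carbon = pd.read_csv(report_dir / "carbon_assay.tsv", sep="\t")
    lines += ["## Carbon-limited flux assay (per mol substrate)", "",
              "| model | substrate | reaction | flux |", "| --- | --- | --- | --- |"]
    for row in carbon.itertuples(index=False):
        lines.append(
            f"| {row.model} | {row.substrate} | {row.reaction} | {row.flux:.4f} |"
        )
    lines.append("")

    text = "\n".join(lines)
    with open(report_dir / "report.md", "w", encoding="utf-8") as handle:
        handle.write(text)
    return text
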