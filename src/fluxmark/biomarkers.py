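"""Flux-range comparison and metabolite biomarker ranking.

Condition-specific models are compared reaction-by-reaction through their
FVA ranges: each shared reaction is classified as ``equivalent`` (both
endpoints equal within tolerance), ``non_overlapping`` (disjoint intervals)
or ``overlapping`` (anything between), with an interval Jaccard index
(intersection length over union length); reactions present in only one arm
are ``absent``.  Classification counts aggregate into a subsystem matrix
(the tabular analogue of a category-by-subsystem heat map), and metabolites
are ranked by how many impacted reactions they participate in — highly
connected metabolites are the candidate biomarkers.  A carbon-limited FBA
assay probes what each model can do per mole of a single carbon substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .errors import InfeasibleModelError
from .lp import DEFAULT_BOUND, TOLERANCE, FvaResult, fba
from .model import MetabolicModel, split_compartment

CATEGORIES = ("non_overlapping", "overlapping", "equivalent")

#: Currency metabolites excluded from connectivity ranking by default.  CoA,
#: ATP and NAD species are deliberately *not* excluded: acyl-CoAs and their
#: relatives are legitimate biomarker candidates.
DEFAULT_EXCLUDED_METABOLITES = frozenset(
    {"h2o", "h", "pi", "ppi", "o2", "co2", "na1", "k"}
)


@dataclass
class ReactionComparison:
    control_range: tuple[float, float] | None
    dose_range: tuple[float, float] | None
    jaccard: float
    category: str


@dataclass
class RangeComparison:
    """Per-reaction flux-range comparison between a control and a dose arm."""

    entries: dict[str, ReactionComparison]
    tolerance: float = TOLERANCE

    def by_category(self, category: str) -> list[str]:
        return [rid for rid, e in self.entries.items() if e.category == category]

    def impacted(self, categories=("non_overlapping", "overlapping")) -> list[str]:
        wanted = set(categories)
        return [rid for rid, e in self.entries.items() if e.category in wanted]


@dataclass
class ConnectivityRanking:
    """Metabolites ordered by participation count in impacted reactions."""

    ranking: list[tuple[str, int]]

    def top(self, n: int) -> list[tuple[str, int]]:
        return self.ranking[:n]

    def rank_of(self, base_id: str) -> int | None:
        """1-based rank, or None if the metabolite does not appear."""
        for position, (met, _) in enumerate(self.ranking, start=1):
            if met == base_id:
                return position
        return None


@dataclass
class VennReport:
    """Region sizes of a three-set reaction Venn decomposition."""

    labels: tuple[str, str, str]
    region_sizes: dict[frozenset, int]
    union_size: int
    fractions_pct: dict[str, float] = field(default_factory=dict)

    @property
    def all_shared_size(self) -> int:
        return self.region_sizes[frozenset(self.labels)]

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "regions": {
                "+".join(sorted(key)): size for key, size in self.region_sizes.items()
            },
            "union_size": self.union_size,
            "all_shared_size": self.all_shared_size,
            "fractions_pct": self.fractions_pct,
        }


def interval_jaccard(
    r1: tuple[float, float], r2: tuple[float, float], tol: float = TOLERANCE
) -> float:
    """Intersection length over union length of two [min, max] intervals.

    Identical point intervals score 1; disjoint intervals score 0; when the
    union is shorter than ``tol`` the intervals are indistinguishable and
    score 1.
    """
    (lo1, hi1), (lo2, hi2) = r1, r2
    if lo1 > hi1 or lo2 > hi2:
        raise ValueError("intervals must satisfy min <= max")
    union = max(hi1, hi2) - min(lo1, lo2)
    if union <= tol:
        return 1.0
    intersection = min(hi1, hi2) - max(lo1, lo2)
    if intersection <= 0:
        return 0.0
    return intersection / union


def classify_ranges(
    fva_control: FvaResult, fva_dose: FvaResult, tol: float = TOLERANCE
) -> RangeComparison:
    """Classify every reaction's control-vs-dose flux ranges.

    ``equivalent``: both endpoints agree within ``tol`` (Jaccard forced to
    1); ``non_overlapping``: intervals separated by more than ``tol``
    (Jaccard 0); ``overlapping``: everything else.  Reactions present in one
    arm only are ``absent``.
    """
    control_ids = set(fva_control.ranges)
    dose_ids = set(fva_dose.ranges)
    shared = control_ids & dose_ids
    if not shared:
        raise ValueError("control and dose FVA results share no reactions")
    entries: dict[str, ReactionComparison] = {}
    for rid in sorted(control_ids | dose_ids):
        control_range = fva_control.ranges.get(rid)
        dose_range = fva_dose.ranges.get(rid)
        if control_range is None or dose_range is None:
            entries[rid] = ReactionComparison(control_range, dose_range, 0.0, "absent")
            continue
        (lo1, hi1), (lo2, hi2) = control_range, dose_range
        if abs(lo1 - lo2) <= tol and abs(hi1 - hi2) <= tol:
            category, jaccard = "equivalent", 1.0
        elif hi1 < lo2 - tol or hi2 < lo1 - tol:
            category, jaccard = "non_overlapping", 0.0
        else:
            category = "overlapping"
            jaccard = interval_jaccard(control_range, dose_range, tol)
        entries[rid] = ReactionComparison(control_range, dose_range, jaccard, category)
    return RangeComparison(entries=entries, tolerance=tol)


def subsystem_matrix(
    comparison: RangeComparison,
    subsystem_of: dict[str, str],
    normalize: str = "by_category",
) -> pd.DataFrame:
    """Subsystem x category membership matrix of the classified reactions.

    ``by_category`` normalizes each category column to sum to 1 (how a
    subsystem is represented *within* a category); ``by_subsystem``
    normalizes rows; ``counts`` leaves raw counts.  Reactions without a
    subsystem label fall under "unassigned".
    """
    if normalize not in ("by_category", "by_subsystem", "counts"):
        raise ValueError(f"unknown normalization {normalize!r}")
    rows: dict[str, dict[str, int]] = {}
    for rid, entry in comparison.entries.items():
        if entry.category not in CATEGORIES:
            continue
        subsystem = subsystem_of.get(rid) or "unassigned"
        rows.setdefault(subsystem, {c: 0 for c in CATEGORIES})
        rows[subsystem][entry.category] += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(CATEGORIES), fill_value=0
    )
    matrix = matrix.sort_index()
    if normalize == "by_category":
        sums = matrix.sum(axis=0)
        matrix = matrix.div(sums.where(sums > 0, 1.0), axis=1)
    elif normalize == "by_subsystem":
        sums = matrix.sum(axis=1)
        matrix = matrix.div(sums.where(sums > 0, 1.0), axis=0)
    return matrix


def metabolite_connectivity(
    comparison: RangeComparison,
    model: MetabolicModel,
    impacted=("non_overlapping", "overlapping"),
    exclude: frozenset | set = DEFAULT_EXCLUDED_METABOLITES,
    merge_compartments: bool = True,
) -> ConnectivityRanking:
    """Rank metabolites by the number of impacted reactions they appear in.

    Compartments are merged on the metabolite base id by default, so e.g.
    cytosolic and mitochondrial carnitine count as one species.  Ties break
    lexicographically for reproducibility.
    """
    impacted_ids = set(comparison.impacted(impacted))
    counts: dict[str, set[str]] = {}
    for reaction in model.reactions:
        if reaction.id not in impacted_ids:
            continue
        for met_id, coeff in reaction.stoichiometry.items():
            if coeff == 0:
                continue
            key = split_compartment(met_id)[0] if merge_compartments else met_id
            if key in exclude:
                continue
            counts.setdefault(key, set()).add(reaction.id)
    ranking = sorted(
        ((met, len(rxns)) for met, rxns in counts.items()),
        key=lambda item: (-item[1], item[0]),
    )
    return ConnectivityRanking(ranking=ranking)


def venn_reactions(reaction_sets: dict[str, set[str]]) -> VennReport:
    """Disjoint-region decomposition of three labeled reaction sets.

    Reports all seven region sizes, the union size, and each region's
    percentage of the union rounded to one decimal.
    """
    if len(reaction_sets) != 3:
        raise ValueError("venn_reactions needs exactly 3 labeled sets")
    if any(not s for s in reaction_sets.values()):
        raise ValueError("all reaction sets must be non-empty")
    labels = tuple(reaction_sets)
    union = set().union(*reaction_sets.values())
    region_sizes: dict[frozenset, int] = {}
    for r in range(1, 4):
        for members in combinations(labels, r):
            inside = set.intersection(*(reaction_sets[l] for l in members))
            outside = set().union(
                *(reaction_sets[l] for l in labels if l not in members), set()
            )
            region_sizes[frozenset(members)] = len(inside - outside)
    fractions = {
        "+".join(sorted(key)): round(100.0 * size / len(union), 1)
        for key, size in region_sizes.items()
    }
    return VennReport(
        labels=labels,
        region_sizes=region_sizes,
        union_size=len(union),
        fractions_pct=fractions,
    )


DEFAULT_FREE_METABOLITES = frozenset({"o2", "h2o", "co2", "h", "pi"})


def carbon_limited_assay(
    model: MetabolicModel,
    substrate_exchange: str,
    amount: float = 1.0,
    objective_id: str | None = None,
    free_metabolites: frozenset | set = DEFAULT_FREE_METABOLITES,
    report_ids=None,
    relax_forced: bool = True,
) -> dict[str, float]:
    """Optimal fluxes per mole of a single carbon substrate.

    Every exchange uptake is closed except the substrate (lower bound
    ``-amount``); exchanges of the listed free metabolites (O2, H2O, CO2,
    protons, phosphate by default) open to the +/-1000 sentinel.  With
    ``relax_forced`` (default) positive lower bounds on internal reactions
    (growth, maintenance) are released so the assay measures pure catabolic
    capability.  Returns the FBA-optimal fluxes of ``report_ids`` (all
    reactions when None); raises on infeasibility.
    """
    if not model.has_reaction(substrate_exchange):
        raise KeyError(f"substrate exchange {substrate_exchange!r} not in model")
    if amount < 0:
        raise ValueError("amount must be non-negative")
    assay = model.copy()
    for reaction in assay.reactions:
        if reaction.is_exchange:
            met_id = next(m for m, c in reaction.stoichiometry.items() if c != 0)
            base_id = split_compartment(met_id)[0]
            if reaction.id == substrate_exchange:
                reaction.lower_bound = -amount
            elif base_id in free_metabolites:
                reaction.lower_bound = -DEFAULT_BOUND
                reaction.upper_bound = DEFAULT_BOUND
            else:
                reaction.lower_bound = max(reaction.lower_bound, 0.0)
        elif relax_forced and reaction.lower_bound > 0:
            reaction.lower_bound = 0.0
    solution = fba(assay, objective_id, "max")
    if not solution.optimal:
        raise InfeasibleModelError(
            f"carbon-limited assay on {substrate_exchange!r} is {solution.status}"
        )
    wanted = list(report_ids) if report_ids is not None else assay.reaction_ids
    return {rid: solution.fluxes[rid] for rid in wanted}


def plot_subsystem_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the subsystem x category matrix as a PNG heat map (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(4 + 0.4 * len(matrix.columns), 1 + 0.3 * len(matrix.index))
    )
    image = ax.imshow(matrix.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=30, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(image, ax=ax, label="share")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
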