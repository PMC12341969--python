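"""Omics integration: turn transcript counts and metabolite abundances into
condition-specific metabolic models.

Transcriptomics: raw counts are log2(n+1)-transformed, each gene's profile is
binarized across samples with a step-function (BASC-A style) threshold,
replicate states are aggregated per condition, and reactions whose GPR
evaluates to 0 get nulled bounds.

Metabolomics: auto-scaled relative abundances (z) rescale a reference AUC
per metabolite, and the scaled availabilities cap exchange-reaction uptake
(lower bound = -kappa * availability).

A :class:`ConditionBundle` pairs the control-arm and dose-arm models for one
exposure level, each built as: exchange-bound scaling -> GPR silencing ->
blocked-reaction pruning, with the imposed constraints recorded as
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleModelError
from .gpr import eval_gpr
from .lp import TOLERANCE, fba, prune_blocked
from .model import MetabolicModel, split_compartment

logger = logging.getLogger(__name__)

#: Numerical guard in the strongest-discontinuity score jump/(error + eps).
BASC_EPSILON = 1e-12

CONDITION_LABELS = ("Low", "Medium", "High")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative count table plus a sample -> condition map."""

    counts: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.condition_of)
        if missing:
            raise ValueError(f"samples without condition assignment: {sorted(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


@dataclass
class BinarizedExpression:
    """Gene x sample binary states plus each gene's threshold."""

    states: pd.DataFrame
    thresholds: pd.Series
    condition_of: dict[str, str]

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.states.columns if self.condition_of[s] == condition]


@dataclass
class MetaboliteAvailability:
    """Scaled metabolite abundances (AUC units, >= 0) for one condition."""

    condition: str
    values: dict[str, float]

    def __post_init__(self):
        negative = {k: v for k, v in self.values.items() if v < 0}
        if negative:
            raise ValueError(f"negative availabilities: {negative}")


@dataclass
class ConditionBundle:
    """Control-arm and dose-arm condition-specific models for one exposure level."""

    control_model: MetabolicModel
    dose_model: MetabolicModel
    label: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"label must be one of {CONDITION_LABELS}, got {self.label!r}"
            )


# ---------------------------------------------------------------------------
# transcriptomics


def log2p1(counts):
    """Elementwise log2(n+1); accepts arrays, Series or DataFrames."""
    values = counts.to_numpy() if hasattr(counts, "to_numpy") else np.asarray(counts)
    if (values < 0).any():
        raise ValueError("log2p1 requires non-negative input")
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(
            np.log2(values + 1.0), index=counts.index, columns=counts.columns
        )
    if isinstance(counts, pd.Series):
        return pd.Series(np.log2(values + 1.0), index=counts.index)
    return np.log2(np.asarray(counts, dtype=float) + 1.0)


def _block_cost(prefix, prefix_sq, i, j):
    """Summed squared deviation of sorted values [i..j] from their mean."""
    count = j - i + 1
    total = prefix[j + 1] - prefix[i]
    total_sq = prefix_sq[j + 1] - prefix_sq[i]
    return total_sq - total * total / count


def _optimal_breaks(sorted_values: np.ndarray, n_breaks: int) -> tuple[list[int], float]:
    """Lexicographically smallest SSE-optimal break set of a given size.

    A break ``b`` separates ``sorted_values[b]`` from ``sorted_values[b+1]``.
    Suffix dynamic program over (start index, remaining breaks), with greedy
    left-to-right reconstruction taking the smallest break that attains the
    global minimum.
    """
    n = len(sorted_values)
    prefix = np.concatenate(([0.0], np.cumsum(sorted_values)))
    prefix_sq = np.concatenate(([0.0], np.cumsum(sorted_values**2)))

    # g[i][k]: minimal SSE of sorted_values[i:] split by k breaks
    g = [[0.0] * (n_breaks + 1) for _ in range(n)]
    for i in range(n):
        g[i][0] = _block_cost(prefix, prefix_sq, i, n - 1)
    for k in range(1, n_breaks + 1):
        for i in range(n - 1 - k, -1, -1):
            g[i][k] = min(
                _block_cost(prefix, prefix_sq, i, b) + g[b + 1][k - 1]
                for b in range(i, n - k)
            )

    breaks: list[int] = []
    i, k = 0, n_breaks
    total = g[0][n_breaks]
    while k > 0:
        for b in range(i, n - k):
            candidate = _block_cost(prefix, prefix_sq, i, b) + g[b + 1][k - 1]
            if candidate == g[i][k]:  # min() returned one candidate exactly
                breaks.append(b)
                i, k = b + 1, k - 1
                break
        else:  # pragma: no cover - guarded by the DP construction
            raise RuntimeError("break reconstruction failed")
    return breaks, total


def _strongest_break(sorted_values: np.ndarray, breaks: list[int], error: float) -> int:
    """Break with maximal jump/(error+eps); ties go to the smallest index."""
    edges = [0] + [b + 1 for b in breaks] + [len(sorted_values)]
    means = [float(np.mean(sorted_values[edges[i]: edges[i + 1]]))
             for i in range(len(edges) - 1)]
    best, best_score = breaks[0], -np.inf
    for pos, b in enumerate(breaks):
        jump = means[pos + 1] - means[pos]
        score = jump / (error + BASC_EPSILON)
        if score > best_score:
            best, best_score = b, score
    return best


def basc_a_binarize(values, min_samples: int = 3) -> tuple[np.ndarray, float]:
    """Binarize a real vector by optimal step-function approximation.

    For every allowed discontinuity count d = 1..n-2 the SSE-optimal
    d-discontinuity step function of the sorted vector is computed by
    dynamic programming; each contributes the midpoint flanking its
    strongest discontinuity (largest jump relative to that step function's
    approximation error) as a candidate threshold.  The final threshold is
    the lower median of the candidates, and values strictly above it map
    to 1.

    Returns ``(binary vector, threshold)``; raises on fewer than
    ``min_samples`` values or a constant vector.
    """
    vector = np.asarray(values, dtype=float)
    n = vector.size
    if n < min_samples or n < 3:
        raise ValueError(f"need at least {max(min_samples, 3)} values, got {n}")
    if np.allclose(vector, vector[0], rtol=0.0, atol=0.0):
        raise ValueError("constant vector cannot be binarized")
    sorted_values = np.sort(vector)

    candidates = []
    for d in range(1, n - 1):
        breaks, error = _optimal_breaks(sorted_values, d)
        b = _strongest_break(sorted_values, breaks, error)
        candidates.append((sorted_values[b] + sorted_values[b + 1]) / 2.0)
    candidates.sort()
    threshold = float(candidates[(len(candidates) - 1) // 2])  # lower median
    return (vector > threshold).astype(int), threshold


def binarize_matrix(matrix: ExpressionMatrix) -> BinarizedExpression:
    """log2(n+1)-transform and binarize every gene's profile across samples.

    Genes with a constant transformed profile carry no scale information;
    they are assigned state 1 everywhere if expressed at all (value > 0)
    and 0 otherwise, with a logged notice.
    """
    transformed = log2p1(matrix.counts)
    states = pd.DataFrame(
        0, index=transformed.index, columns=transformed.columns, dtype=int
    )
    thresholds = pd.Series(np.nan, index=transformed.index, dtype=float)
    constant_genes = []
    for gene, row in transformed.iterrows():
        vector = row.to_numpy()
        if np.all(vector == vector[0]):
            constant_genes.append(gene)
            states.loc[gene] = int(vector[0] > 0)
            continue
        binary, threshold = basc_a_binarize(vector)
        states.loc[gene] = binary
        thresholds[gene] = threshold
    if constant_genes:
        logger.info(
            "%d genes with constant expression kept at their flat state",
            len(constant_genes),
        )
    return BinarizedExpression(
        states=states, thresholds=thresholds, condition_of=dict(matrix.condition_of)
    )


def gene_condition_state(
    binarized: BinarizedExpression, condition: str, rule: str = "majority"
) -> dict[str, int]:
    """Aggregate replicate binary states into one state per gene.

    Rules: ``any`` (max), ``all`` (min), ``majority`` (ties resolve to 1,
    the non-penalizing default for n=2 replicate designs).
    """
    samples = binarized.samples_for(condition)
    if not samples:
        raise KeyError(f"no samples for condition {condition!r}")
    block = binarized.states[samples]
    if rule == "any":
        aggregated = block.max(axis=1)
    elif rule == "all":
        aggregated = block.min(axis=1)
    elif rule == "majority":
        aggregated = (block.sum(axis=1) * 2 >= len(samples)).astype(int)
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    return {gene: int(state) for gene, state in aggregated.items()}


# ---------------------------------------------------------------------------
# metabolomics


def scale_metabolomics(
    reference_auc: dict[str, float],
    autoscaled_values: dict[str, float],
    mode: str = "exp2",
    condition: str = "",
) -> MetaboliteAvailability:
    """Rescale reference AUCs by auto-scaled relative abundances z.

    ``exp2`` mode multiplies by 2**z (z read as a log2 shift);
    ``multiplicative`` multiplies by max(0, 1+z) (z read as a relative
    change, floored at zero).  Metabolites without a z keep their reference
    AUC; z values without a reference are ignored with a logged notice.
    """
    if any(v < 0 for v in reference_auc.values()):
        raise ValueError("reference AUCs must be non-negative")
    if mode not in ("exp2", "multiplicative"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    unmatched = set(autoscaled_values) - set(reference_auc)
    if unmatched:
        logger.info(
            "z values for metabolites without reference AUC ignored: %s",
            ", ".join(sorted(unmatched)),
        )
    values = {}
    for met, auc in reference_auc.items():
        z = autoscaled_values.get(met)
        if z is None:
            values[met] = auc
        elif mode == "exp2":
            values[met] = auc * 2.0**z
        else:
            values[met] = auc * max(0.0, 1.0 + z)
    return MetaboliteAvailability(condition=condition, values=values)


def availability_to_exchange_bounds(
    model: MetabolicModel,
    availability: MetaboliteAvailability,
    kappa: float = 1.0,
) -> MetabolicModel:
    """Cap exchange uptake in proportion to metabolite availability.

    For every exchange reaction whose metabolite base id has an
    availability ``a``, the lower bound becomes ``-kappa * a`` (uptake
    capacity); zero availability closes uptake.  Exchanges without data are
    untouched.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    scaled = model.copy()
    matched = set()
    for reaction in scaled.reactions:
        if not reaction.is_exchange:
            continue
        met_id = next(m for m, c in reaction.stoichiometry.items() if c != 0)
        base_id = split_compartment(met_id)[0]
        if base_id in availability.values:
            reaction.lower_bound = -kappa * availability.values[base_id]
            matched.add(base_id)
    unmatched = set(availability.values) - matched
    if unmatched:
        logger.info(
            "availabilities without a matching exchange left unused: %s",
            ", ".join(sorted(unmatched)),
        )
    return scaled


# ---------------------------------------------------------------------------
# condition-specific models


def silence_unexpressed(
    model: MetabolicModel, gene_states: dict[str, int]
) -> MetabolicModel:
    """Null the bounds of gene-associated reactions whose GPR evaluates to 0.

    Reactions with an empty GPR (transport, exchange, pseudo-reactions) are
    untouched: nulling non-gene-associated reactions would close boundary
    fluxes wholesale.
    """
    silenced = model.copy()
    for reaction in silenced.reactions:
        if reaction.gpr and eval_gpr(reaction.gpr, gene_states) == 0:
            reaction.lower_bound = 0.0
            reaction.upper_bound = 0.0
    return silenced


def _bound_changes(before: MetabolicModel, after: MetabolicModel) -> list[str]:
    bounds = {r.id: (r.lower_bound, r.upper_bound) for r in before.reactions}
    changes = []
    for reaction in after.reactions:
        old = bounds.get(reaction.id)
        new = (reaction.lower_bound, reaction.upper_bound)
        if old is not None and old != new:
            changes.append(f"{reaction.id}: bounds {old} -> {new}")
    return changes


def build_condition_model(
    base_model: MetabolicModel,
    gene_states: dict[str, int],
    availability: MetaboliteAvailability,
    kappa: float = 1.0,
    objective_id: str | None = None,
) -> tuple[MetabolicModel, list[str]]:
    """One arm of a bundle: scale exchanges, silence, prune; with provenance."""
    scaled = availability_to_exchange_bounds(base_model, availability, kappa)
    provenance = [
        f"[{availability.condition}] {line}" for line in _bound_changes(base_model, scaled)
    ]
    silenced = silence_unexpressed(scaled, gene_states)
    provenance += [
        f"[{availability.condition}] {line}" for line in _bound_changes(scaled, silenced)
    ]
    pruned, removed = prune_blocked(silenced)
    provenance += [
        f"[{availability.condition}] removed blocked reaction {rid}" for rid in removed
    ]
    objective = objective_id or pruned.objective_id
    if objective and not pruned.has_reaction(objective):
        raise InfeasibleModelError(
            f"objective reaction {objective!r} was pruned from the "
            f"{availability.condition} model; review kappa and constraints"
        )
    if objective:
        solution = fba(pruned, objective, "max")
        if not solution.optimal or solution.objective_value < TOLERANCE:
            raise InfeasibleModelError(
                f"{availability.condition} model cannot sustain ATP demand "
                f"(status {solution.status}); review kappa and imposed constraints"
            )
    return pruned, provenance


def build_condition_bundle(
    base_model: MetabolicModel,
    expression: BinarizedExpression,
    availability_control: MetaboliteAvailability,
    availability_dose: MetaboliteAvailability,
    label: str,
    rule: str = "majority",
    kappa: float = 1.0,
    objective_id: str | None = None,
) -> ConditionBundle:
    """Build the paired control/dose condition-specific models for one level."""
    control_states = gene_condition_state(expression, availability_control.condition, rule)
    dose_states = gene_condition_state(expression, availability_dose.condition, rule)
    control_model, control_prov = build_condition_model(
        base_model, control_states, availability_control, kappa, objective_id
    )
    dose_model, dose_prov = build_condition_model(
        base_model, dose_states, availability_dose, kappa, objective_id
    )
    return ConditionBundle(
        control_model=control_model,
        dose_model=dose_model,
        label=label,
        provenance=control_prov + dose_prov,
    )
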