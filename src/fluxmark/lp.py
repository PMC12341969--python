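"""Flux balance analysis (FBA), flux variability analysis (FVA) and
blocked-reaction pruning on top of scipy's HiGHS linear-programming solver.

FBA solves ``max/min v_obj`` over the flux polytope
``{v : S v = 0, lb <= v <= ub}``.  FVA then minimizes and maximizes each
reaction's flux over the optimal face ``{v : v_obj >= fraction * opt}``;
with ``objective_fraction = 1.0`` (the default) that is the face of optimal
objective flux, so every FVA interval brackets the FBA optimum's flux.

Only objective values and FVA interval endpoints are contractual: flux
vectors at degenerate optima depend on the solver's vertex choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleModelError
from .model import DEFAULT_BOUND, MetabolicModel

#: Shared absolute numerical tolerance: feasibility checks, blocked-reaction
#: detection, and flux-interval comparisons all use this single constant.
TOLERANCE = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    """Per-reaction [min, max] attainable flux at a fixed objective fraction."""

    ranges: dict[str, tuple[float, float]]
    objective_id: str
    objective_fraction: float = 1.0
    objective_value: float = field(default=float("nan"))

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.ranges

    def __iter__(self):
        return iter(self.ranges)


def _solve(c, A_eq, bounds):
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds,
        method="highs",
    )


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Optimize one reaction's flux over the steady-state flux polytope."""
    objective_id = objective_id or model.objective_id
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, _, rxn_index = model.stoichiometric_matrix()
    if objective_id not in rxn_index:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    n = len(model.reactions)
    c = np.zeros(n)
    c[rxn_index[objective_id]] = -1.0 if direction == "max" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    result = _solve(c, S, bounds)
    status = _STATUS.get(result.status, "error")
    if status != "optimal":
        return FluxSolution(objective_value=float("nan"), fluxes={}, status=status)
    sign = -1.0 if direction == "max" else 1.0
    fluxes = {r.id: float(result.x[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(
        objective_value=float(sign * result.fun), fluxes=fluxes, status="optimal"
    )


def fva(
    model: MetabolicModel,
    objective_id: str | None = None,
    objective_fraction: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> FvaResult:
    """Min/max flux per reaction over the (near-)optimal face of the polytope.

    ``objective_fraction`` keeps ``v_obj >= fraction * opt`` (stated for
    non-negative optima, the constraint-based convention); 1.0 pins the
    objective at its optimum.
    """
    objective_id = objective_id or model.objective_id
    if not (0.0 < objective_fraction <= 1.0):
        raise ValueError("objective_fraction must be in (0, 1]")
    solution = fba(model, objective_id, "max")
    if not solution.optimal:
        raise InfeasibleModelError(
            f"FBA on objective {objective_id!r} is {solution.status}; FVA aborted"
        )
    opt = solution.objective_value

    S, _, rxn_index = model.stoichiometric_matrix()
    bounds = [[r.lower_bound, r.upper_bound] for r in model.reactions]
    obj_j = rxn_index[objective_id]
    floor = objective_fraction * opt if opt >= 0 else opt / objective_fraction
    bounds[obj_j][0] = max(bounds[obj_j][0], floor)

    targets = list(reactions) if reactions is not None else model.reaction_ids
    n = len(model.reactions)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rxn_index[rid]
        lo, hi = None, None
        for sign, slot in ((1.0, "lo"), (-1.0, "hi")):
            c = np.zeros(n)
            c[j] = sign
            result = _solve(c, S, bounds)
            if _STATUS.get(result.status, "error") != "optimal":
                raise InfeasibleModelError(
                    f"FVA subproblem for {rid!r} returned "
                    f"{_STATUS.get(result.status, 'error')}"
                )
            value = float(sign * result.fun)
            if slot == "lo":
                lo = value
            else:
                hi = value
        # clamp the tiny solver-noise inversions a pair of LPs can produce
        if lo > hi:
            lo = hi = (lo + hi) / 2.0
        ranges[rid] = (lo, hi)
    return FvaResult(
        ranges=ranges,
        objective_id=objective_id,
        objective_fraction=objective_fraction,
        objective_value=opt,
    )


def _flux_spans(model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """FVA with all exchange bounds opened and no objective constraint."""
    probe = model.copy()
    for reaction in probe.reactions:
        if reaction.is_exchange:
            reaction.lower_bound = -DEFAULT_BOUND
            reaction.upper_bound = DEFAULT_BOUND
    S, _, _ = probe.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in probe.reactions]
    n = len(probe.reactions)
    spans = {}
    for j, reaction in enumerate(probe.reactions):
        extremes = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            result = _solve(c, S, bounds)
            if _STATUS.get(result.status, "error") != "optimal":
                raise InfeasibleModelError(
                    f"consistency probe for {reaction.id!r} returned "
                    f"{_STATUS.get(result.status, 'error')}"
                )
            extremes.append(float(sign * result.fun))
        spans[reaction.id] = (extremes[0], extremes[1])
    return spans


def prune_blocked(
    model: MetabolicModel, tolerance: float = TOLERANCE
) -> tuple[MetabolicModel, list[str]]:
    """Remove reactions that cannot carry flux under any exchange regime.

    A reaction is blocked when its attainable flux interval lies inside
    ``[-tolerance, +tolerance]`` with every exchange opened to the +/-1000
    sentinel and no objective imposed (pure stoichiometry/bounds
    consistency).  Removal is iterated to a fixpoint; surviving reactions
    keep their original bounds.  Metabolites left unreferenced are dropped.
    """
    current = model.copy()
    removed: list[str] = []
    while True:
        if not current.reactions:
            break
        spans = _flux_spans(current)
        blocked = [
            rid
            for rid, (lo, hi) in spans.items()
            if abs(lo) <= tolerance and abs(hi) <= tolerance
        ]
        if not blocked:
            break
        removed.extend(blocked)
        blocked_set = set(blocked)
        current.reactions = [r for r in current.reactions if r.id not in blocked_set]
    referenced: set[str] = set()
    for reaction in current.reactions:
        referenced.update(reaction.stoichiometry)
    current.metabolites = [m for m in current.metabolites if m.id in referenced]
    return current, removed


def atp_yield_assay(model: MetabolicModel, objective_id: str | None = None) -> float:
    """Maximal flux through the ATP demand reaction (metabolic-capacity proxy)."""
    solution = fba(model, objective_id, "max")
    if not solution.optimal:
        raise InfeasibleModelError(f"ATP yield assay: model is {solution.status}")
    return solution.objective_value


def steady_state_residual(model: MetabolicModel, fluxes: dict[str, float]) -> float:
    """max |S v| for a flux dict — the mass-conservation residual."""
    S, _, rxn_index = model.stoichiometric_matrix()
    v = np.zeros(len(model.reactions))
    for rid, value in fluxes.items():
        v[rxn_index[rid]] = value
    if S.size == 0:
        return 0.0
    return float(np.max(np.abs(S @ v)))
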