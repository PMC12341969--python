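"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: LP results are
checked against exhaustive vertex enumeration of the flux polytope, the
binarization against exhaustive enumeration of all break sets, and GPR
evaluation against Python's own boolean semantics.
"""

from __future__ import annotations

import itertools

import numpy as np


def _independent_rows(A: np.ndarray) -> np.ndarray:
    rows: list[int] = []
    for i in range(A.shape[0]):
        if np.linalg.matrix_rank(A[rows + [i]]) > len(rows):
            rows.append(i)
    return A[rows]


def enumerate_vertices(A_eq, lb, ub, tol: float = 1e-9) -> list[np.ndarray]:
    """All vertices of {x : A_eq x = 0, lb <= x <= ub} via basis enumeration."""
    A = _independent_rows(np.asarray(A_eq, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    r, n = A.shape
    vertices: list[np.ndarray] = []
    if r == 0:
        for corner in itertools.product(*zip(lb, ub)):
            vertices.append(np.array(corner))
        return vertices
    for basis in itertools.combinations(range(n), r):
        B = A[:, basis]
        if abs(np.linalg.det(B)) < 1e-10:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for assignment in itertools.product((0, 1), repeat=len(nonbasic)):
            x = np.zeros(n)
            for j, at_upper in zip(nonbasic, assignment):
                x[j] = ub[j] if at_upper else lb[j]
            x[list(basis)] = np.linalg.solve(B, -A[:, nonbasic] @ x[nonbasic])
            if np.all(x >= lb - tol) and np.all(x <= ub + tol):
                vertices.append(np.clip(x, lb, ub))
    return vertices


def fba_by_enumeration(S, lb, ub, objective_index: int) -> float:
    """Max objective flux over the polytope, by vertex enumeration."""
    vertices = enumerate_vertices(S, lb, ub)
    assert vertices, "flux polytope has no vertices"
    return max(v[objective_index] for v in vertices)


def fva_by_enumeration(S, lb, ub, objective_index: int, fraction: float = 1.0):
    """FVA intervals over the (near-)optimal face, by vertex enumeration.

    The objective floor v_obj >= fraction * opt is added as an equality
    with a bounded slack variable so the face's vertices stay enumerable.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    opt = fba_by_enumeration(S, lb, ub, objective_index)
    floor = fraction * opt if opt >= 0 else opt / fraction
    m, n = S.shape
    A_aug = np.zeros((m + 1, n + 1))
    A_aug[:m, :n] = S
    A_aug[m, objective_index] = 1.0
    A_aug[m, n] = -1.0
    # v_obj - s = floor is encoded by shifting s's bounds
    slack_ub = max(ub[objective_index] - floor, 0.0)
    lb_aug = np.concatenate([lb, [0.0]])
    ub_aug = np.concatenate([ub, [slack_ub]])
    # change of variable: s' = s + floor so the system stays homogeneous
    lb_aug[n] = floor
    ub_aug[n] = floor + slack_ub
    vertices = enumerate_vertices(A_aug, lb_aug, ub_aug)
    assert vertices, "optimal face has no vertices"
    return [
        (min(v[j] for v in vertices), max(v[j] for v in vertices))
        for j in range(n)
    ]


def random_network(rng: np.random.Generator, max_reactions: int = 8):
    """Small random stoichiometric system with 0 always feasible."""
    n = int(rng.integers(4, max_reactions + 1))
    m = int(rng.integers(2, 5))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    for j in range(n):
        if not S[:, j].any():
            S[int(rng.integers(0, m)), j] = 1.0
    lb = rng.integers(-10, 1, size=n).astype(float)
    ub = rng.integers(0, 11, size=n).astype(float)
    objective = int(rng.integers(0, n))
    return S, lb, ub, objective


def basc_bruteforce(values, eps: float = 1e-12):
    """Reference binarization: exhaustive enumeration over all break sets.

    For each discontinuity count d the SSE-minimal break set is found by
    enumerating all C(n-1, d) subsets (first strict minimum in
    lexicographic order); the strongest break maximizes jump/(SSE+eps)
    (ties to the smallest index); the threshold is the lower median of the
    per-d candidates; binarization is value > threshold.
    """
    original = np.asarray(values, dtype=float)
    v = np.sort(original)
    n = v.size

    def sse_of(breaks):
        edges = [0] + [b + 1 for b in breaks] + [n]
        return sum(
            float(np.sum((v[a:b] - np.mean(v[a:b])) ** 2))
            for a, b in zip(edges, edges[1:])
        )

    candidates = []
    for d in range(1, n - 1):
        best_breaks, best_sse = None, np.inf
        for breaks in itertools.combinations(range(n - 1), d):
            sse = sse_of(breaks)
            if sse < best_sse:
                best_breaks, best_sse = breaks, sse
        edges = [0] + [b + 1 for b in best_breaks] + [n]
        means = [float(np.mean(v[a:b])) for a, b in zip(edges, edges[1:])]
        strongest, best_score = best_breaks[0], -np.inf
        for pos, b in enumerate(best_breaks):
            score = (means[pos + 1] - means[pos]) / (best_sse + eps)
            if score > best_score:
                strongest, best_score = b, score
        candidates.append((v[strongest] + v[strongest + 1]) / 2.0)
    candidates.sort()
    threshold = candidates[(len(candidates) - 1) // 2]
    return (original > threshold).astype(int), float(threshold)


def random_gpr(rng: np.random.Generator, genes: list[str], depth: int = 0) -> str:
    """Random and/or/parenthesis expression over the given gene ids."""
    if depth >= 3 or rng.random() < 0.35:
        return genes[int(rng.integers(0, len(genes)))]
    op = " and " if rng.random() < 0.5 else " or "
    k = int(rng.integers(2, 4))
    parts = [random_gpr(rng, genes, depth + 1) for _ in range(k)]
    return "(" + op.join(parts) + ")"
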