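"""Independent oracles used by the test suite.

These deliberately avoid the package's LP code paths: the vertex enumerator
solves square linear systems by brute force over active bound sets, and the
ratio bisector calls scipy.optimize.linprog directly on a hand-assembled
problem.  They are only practical on tiny models (<= 8 reactions).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from respitraits.core import MetabolicModel

TOL = 1e-9


def _stoich_matrix(model: MetabolicModel):
    mids = [m.id for m in model.metabolites if not m.is_boundary]
    midx = {mid: i for i, mid in enumerate(mids)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(mids), len(rids)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            if mid in midx:
                S[midx[mid], j] += coef
    return S, rids


def enumerate_vertices(model: MetabolicModel):
    """All vertices of {v : S v = 0, lb <= v <= ub} by active-set brute force.

    A vertex has at least n - rank(S) variables at a bound; we enumerate every
    choice of fixed variables and bound sides, solve the remaining square
    system by least squares, and keep feasible solutions.
    """
    S, rids = _stoich_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    n = len(rids)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for sides in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, side in zip(fixed, sides):
                v[j] = lb[j] if side == 0 else ub[j]
            if free:
                A = S[:, free]
                b = -S[:, fixed] @ v[list(fixed)]
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                if np.linalg.norm(A @ sol - b, ord=np.inf) > 1e-7:
                    continue  # inconsistent system: not a vertex
                v[free] = sol
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7) \
                    and np.linalg.norm(S @ v, ord=np.inf) < 1e-7:
                vertices.append(v)
    return vertices, rids


def fba_by_vertex_enumeration(model: MetabolicModel) -> float:
    """Best objective value over all enumerated vertices (LP optimum oracle)."""
    vertices, rids = enumerate_vertices(model)
    if not vertices:
        raise ValueError("no feasible vertex found")
    c = np.zeros(len(rids))
    for rid, w in model.objective.items():
        c[rids.index(rid)] = w
    return max(float(c @ v) for v in vertices)


def min_ratio_by_bisection(model: MetabolicModel,
                           numerator_fwd: dict[str, float],
                           numerator_rev: dict[str, float],
                           denominator: dict[str, float],
                           lo: float = 0.0, hi: float = 1e3,
                           iterations: int = 64) -> float:
    """Bisection on r: is there a feasible v with num(v) <= r * den(v), den > 0?

    Assembles the split-variable LP with scipy.optimize.linprog directly:
    minimize (num - r*den) over the polytope intersected with den(v) >= d0.
    """
    mids = [m.id for m in model.metabolites if not m.is_boundary]
    midx = {mid: i for i, mid in enumerate(mids)}
    rids = [r.id for r in model.reactions]
    n = len(rids)
    rev = [j for j, r in enumerate(model.reactions) if r.lower_bound < 0]
    rev_pos = {j: n + k for k, j in enumerate(rev)}
    nv = n + len(rev)

    A_eq = np.zeros((len(mids), nv))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            if mid in midx:
                A_eq[midx[mid], j] += coef
                if j in rev_pos:
                    A_eq[midx[mid], rev_pos[j]] -= coef
    b_eq = np.zeros(len(mids))

    bounds = []
    for j, r in enumerate(model.reactions):
        bounds.append((max(0.0, r.lower_bound), max(0.0, r.upper_bound)))
    for j in rev:
        pass
    for j in rev:
        bounds.append((0.0, max(0.0, -model.reactions[j].lower_bound)))

    den = np.zeros(nv)
    for rid, w in denominator.items():
        j = rids.index(rid)
        den[j] = w
        if j in rev_pos:
            den[rev_pos[j]] = -w
    num = np.zeros(nv)
    for rid, w in numerator_fwd.items():
        num[rids.index(rid)] += w
    for rid, w in numerator_rev.items():
        j = rids.index(rid)
        if j in rev_pos:
            num[rev_pos[j]] += w

    d0 = 1e-3  # positive-denominator floor

    def achievable(r: float) -> bool:
        res = linprog(num - r * den, A_ub=-den.reshape(1, -1), b_ub=[-d0],
                      A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        return res.status == 0 and res.fun <= 1e-9

    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if achievable(mid):
            hi = mid
        else:
            lo = mid
    return hi
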