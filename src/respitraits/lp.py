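"""Steady-state flux computation over a scipy (HiGHS) linear-programming backend.

Implements flux balance analysis (FBA), parsimonious FBA with an optional
lexicographic flux-pinning pass, constrained maximization of an arbitrary
linear flux expression, the Charnes-Cooper linear-fractional minimizer used
for respiration-per-carbon optimization, and reaction knockouts.

All computations are deterministic given model + options; no randomness is
involved anywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .core import MetabolicModel

logger = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6


class LPError(RuntimeError):
    pass


@dataclass
class LinearConstraint:
    """A linear constraint over net reaction fluxes: sum(coef_r * v_r) <sense> rhs."""

    coefficients: dict[str, float]
    sense: str  # "<=", ">=", "="
    rhs: float

    def __post_init__(self) -> None:
        if self.sense not in ("<=", ">=", "="):
            raise ValueError(f"unknown constraint sense {self.sense!r}")


@dataclass
class FluxDistribution:
    model_id: str
    flux: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"
    tolerance: float = FEASIBILITY_TOL
    #: free-form solver metadata (backend, lexicographic flag, ...)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, reaction_id: str) -> float:
        return self.flux[reaction_id]


def _status_from_scipy(res) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")


class LPBackend:
    """Narrow LP interface: load a problem, solve, report status and solution.

    The default (and only shipped) implementation calls
    ``scipy.optimize.linprog(method="highs")``.  Swapping solvers means
    subclassing and overriding :meth:`solve`.
    """

    def solve(self, c, A_eq, b_eq, A_ub, b_ub, bounds):
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        return _status_from_scipy(res), res.x, res.fun


_DEFAULT_BACKEND = LPBackend()


class _Problem:
    """Assembles S·v = 0 plus extra constraints for a model, in reaction order."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rids = [r.id for r in model.reactions]
        self.ridx = {rid: i for i, rid in enumerate(self.rids)}
        mids = [m.id for m in model.metabolites]
        midx = {mid: i for i, mid in enumerate(mids)}
        S = lil_matrix((len(mids), len(self.rids)))
        for j, r in enumerate(model.reactions):
            for mid, coef in r.stoichiometry.items():
                if not model.met[mid].is_boundary:
                    S[midx[mid], j] += coef
        # drop boundary-metabolite rows entirely (they are unconstrained pools)
        keep = [i for i, m in enumerate(model.metabolites) if not m.is_boundary]
        self.S = S.tocsr()[keep, :]
        self.lb = np.array([r.lower_bound for r in model.reactions])
        self.ub = np.array([r.upper_bound for r in model.reactions])

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.rids))
        for rid, w in self.model.objective.items():
            c[self.ridx[rid]] = w
        return c

    def expression_vector(self, coefficients: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.rids))
        for rid, w in coefficients.items():
            if rid not in self.ridx:
                raise KeyError(f"unknown reaction {rid!r} in linear expression")
            c[self.ridx[rid]] = w
        return c

    def constraint_rows(self, constraints):
        """Return (A_ub, b_ub, A_eq_extra, b_eq_extra) dense arrays."""
        n = len(self.rids)
        ub_rows, ub_rhs, eq_rows, eq_rhs = [], [], [], []
        for con in constraints or []:
            row = self.expression_vector(con.coefficients)
            if con.sense == "<=":
                ub_rows.append(row); ub_rhs.append(con.rhs)
            elif con.sense == ">=":
                ub_rows.append(-row); ub_rhs.append(-con.rhs)
            else:
                eq_rows.append(row); eq_rhs.append(con.rhs)
        A_ub = np.array(ub_rows) if ub_rows else np.zeros((0, n))
        A_eq = np.array(eq_rows) if eq_rows else np.zeros((0, n))
        return A_ub, np.array(ub_rhs), A_eq, np.array(eq_rhs)


def _solve_net(problem: _Problem, c: np.ndarray, sense: str,
               extra_constraints, backend: LPBackend):
    """Solve over net fluxes; returns (status, v, objective)."""
    A_ub, b_ub, A_eq_x, b_eq_x = problem.constraint_rows(extra_constraints)
    A_eq = np.vstack([problem.S.toarray(), A_eq_x]) if A_eq_x.size else problem.S.toarray()
    b_eq = np.concatenate([np.zeros(problem.S.shape[0]), b_eq_x]) if A_eq_x.size \
        else np.zeros(problem.S.shape[0])
    sign = -1.0 if sense == "max" else 1.0
    bounds = list(zip(problem.lb, problem.ub))
    status, x, fun = backend.solve(sign * c, A_eq, b_eq,
                                   A_ub if A_ub.size else None,
                                   b_ub if A_ub.size else None, bounds)
    if status != "optimal":
        return status, None, float("nan")
    return status, x, sign * fun


def fba(model: MetabolicModel,
        extra_constraints: list[LinearConstraint] | None = None,
        backend: LPBackend = _DEFAULT_BACKEND) -> FluxDistribution:
    """Maximize the model objective subject to S·v = 0, bounds, extra constraints."""
    if not model.objective:
        raise LPError(f"model {model.id} has an empty objective")
    problem = _Problem(model)
    status, x, obj = _solve_net(problem, problem.objective_vector(), "max",
                                extra_constraints, backend)
    flux = dict(zip(problem.rids, x)) if x is not None else {}
    return FluxDistribution(model_id=model.id, flux=flux,
                            objective_value=obj, status=status,
                            meta={"method": "fba"})


def maximize_flux(model: MetabolicModel, target: dict[str, float],
                  fixed_objective_fraction: float = 1.0,
                  extra_constraints: list[LinearConstraint] | None = None,
                  backend: LPBackend = _DEFAULT_BACKEND) -> FluxDistribution:
    """Maximize a linear flux expression at a fixed fraction of the FBA optimum."""
    base = fba(model, extra_constraints, backend)
    if base.status != "optimal":
        return base
    constraints = list(extra_constraints or [])
    constraints.append(LinearConstraint(
        coefficients=dict(model.objective), sense=">=",
        rhs=fixed_objective_fraction * base.objective_value))
    problem = _Problem(model)
    status, x, obj = _solve_net(problem, problem.expression_vector(target), "max",
                                constraints, backend)
    flux = dict(zip(problem.rids, x)) if x is not None else {}
    return FluxDistribution(model_id=model.id, flux=flux, objective_value=obj,
                            status=status, meta={"method": "maximize_flux"})


# ----------------------------------------------------------------------
# Parsimonious FBA on split (irreversible) variables
# ----------------------------------------------------------------------

class _SplitProblem:
    """Every reversible reaction (lb < 0 < ub, or lb < 0) is split into a
    forward and a reverse nonnegative half; strictly irreversible reactions
    keep a single variable.  Net flux v = f - r."""

    def __init__(self, problem: _Problem):
        self.problem = problem
        n = len(problem.rids)
        self.fwd_idx = np.arange(n)
        rev_cols = [j for j in range(n) if problem.lb[j] < 0]
        self.rev_pos = {j: n + k for k, j in enumerate(rev_cols)}
        self.rev_cols = rev_cols
        self.n_net = n
        self.n_vars = n + len(rev_cols)

    def lift(self, row: np.ndarray) -> np.ndarray:
        """Lift a net-flux coefficient row to split variables (v = f - r)."""
        out = np.zeros(self.n_vars)
        out[: self.n_net] = row
        for j in self.rev_cols:
            out[self.rev_pos[j]] = -row[j]
        return out

    def bounds(self):
        lo = np.zeros(self.n_vars)
        hi = np.zeros(self.n_vars)
        for j in range(self.n_net):
            hi[j] = max(0.0, self.problem.ub[j])
            lo[j] = max(0.0, self.problem.lb[j])
        for j in self.rev_cols:
            hi[self.rev_pos[j]] = max(0.0, -self.problem.lb[j])
        return list(zip(lo, hi))

    def recombine(self, x: np.ndarray) -> np.ndarray:
        v = x[: self.n_net].copy()
        for j in self.rev_cols:
            v[j] -= x[self.rev_pos[j]]
        return v

    def total_flux_vector(self) -> np.ndarray:
        return np.ones(self.n_vars)

    def assemble(self, extra_constraints):
        prob = self.problem
        A_ub_x, b_ub_x, A_eq_x, b_eq_x = prob.constraint_rows(extra_constraints)
        S = prob.S.toarray()
        A_eq = np.array([self.lift(S[i]) for i in range(S.shape[0])]) if S.shape[0] \
            else np.zeros((0, self.n_vars))
        b_eq = np.zeros(S.shape[0])
        if A_eq_x.size:
            A_eq = np.vstack([A_eq, [self.lift(r) for r in A_eq_x]])
            b_eq = np.concatenate([b_eq, b_eq_x])
        A_ub = np.array([self.lift(r) for r in A_ub_x]) if A_ub_x.size \
            else np.zeros((0, self.n_vars))
        return A_ub, b_ub_x, A_eq, b_eq


def pfba(model: MetabolicModel,
         extra_constraints: list[LinearConstraint] | None = None,
         optimum_fraction: float = 1.0,
         lexicographic: bool = False,
         backend: LPBackend = _DEFAULT_BACKEND) -> FluxDistribution:
    """Parsimonious FBA: fix the objective at ``optimum_fraction`` of the FBA
    optimum and minimize the sum of absolute fluxes.

    With ``lexicographic=True`` a deterministic tie-breaking pass follows:
    the total-flux optimum is fixed and each reaction's absolute flux is
    minimized and pinned in reaction-id order, so the reported distribution
    is unique regardless of LP backend.
    """
    if not (0.0 < optimum_fraction <= 1.0):
        raise ValueError("optimum_fraction must be in (0, 1]")
    base = fba(model, extra_constraints, backend)
    if base.status != "optimal":
        return base

    problem = _Problem(model)
    split = _SplitProblem(problem)
    constraints = list(extra_constraints or [])
    constraints.append(LinearConstraint(
        coefficients=dict(model.objective), sense=">=",
        rhs=optimum_fraction * base.objective_value))
    A_ub, b_ub, A_eq, b_eq = split.assemble(constraints)
    bounds = split.bounds()
    c_total = split.total_flux_vector()

    status, x, total = backend.solve(c_total, A_eq, b_eq,
                                              A_ub if A_ub.size else None,
                                              b_ub if A_ub.size else None, bounds)
    if status != "optimal":
        return FluxDistribution(model_id=model.id, flux={}, objective_value=float("nan"),
                                status=status, meta={"method": "pfba"})

    if lexicographic:
        # Pin total flux, then minimize each reaction's |flux| in id order.
        # Each pin gets a 1e-7 relative slack: tight enough that trait values
        # are stable to ~1e-7, loose enough that the stacked near-equalities
        # stay numerically feasible for the solver.
        def slack(value: float) -> float:
            return value + 1e-7 * (1.0 + abs(value))

        rows = [c_total]
        rhs = [slack(total)]
        order = sorted(range(split.n_net), key=lambda j: problem.rids[j])
        for j in order:
            row = np.zeros(split.n_vars)
            row[j] = 1.0
            if j in split.rev_pos:
                row[split.rev_pos[j]] = 1.0
            if float(row @ x) <= 1e-12:
                # already at the provable minimum of a nonnegative sum:
                # pin without an extra solve
                rows.append(row)
                rhs.append(slack(0.0))
                continue
            A_ub_j = np.vstack([A_ub, rows]) if A_ub.size else np.array(rows)
            b_ub_j = np.concatenate([b_ub, rhs])
            status, x_j, val = backend.solve(row, A_eq, b_eq, A_ub_j, b_ub_j, bounds)
            if status != "optimal":  # numerical hiccup: keep previous solution
                logger.warning("lexicographic pass failed at %s; keeping prior point",
                               problem.rids[j])
                break
            x = x_j
            rows.append(row)
            rhs.append(slack(val))

    v = split.recombine(x)
    c_obj = problem.objective_vector()
    return FluxDistribution(
        model_id=model.id, flux=dict(zip(problem.rids, v)),
        objective_value=float(c_obj @ v), status="optimal",
        meta={"method": "pfba", "total_flux": float(np.abs(v).sum()),
              "lexicographic": lexicographic, "fba_optimum": base.objective_value},
    )


# ----------------------------------------------------------------------
# Linear-fractional minimization (Charnes-Cooper)
# ----------------------------------------------------------------------

def minimize_linear_fractional(
        model: MetabolicModel,
        numerator: dict[str, float] | tuple[dict[str, float], dict[str, float]],
        denominator: dict[str, float],
        extra_constraints: list[LinearConstraint] | None = None,
        backend: LPBackend = _DEFAULT_BACKEND) -> FluxDistribution:
    """Minimize numerator(v) / denominator(v) over the flux polytope.

    Uses the Charnes-Cooper substitution y = t*v, t >= 0: minimize num(y)
    subject to S*y = 0, den(y) = 1, t*lb <= y <= t*ub.  The achieved ratio is
    returned as ``objective_value`` and v = y / t as the flux vector.

    ``numerator`` may be a plain net-flux expression, or a pair
    ``(forward_coeffs, reverse_coeffs)`` applied to the rectified forward and
    reverse parts of each flux (needed for direction-aware CO2-production
    sums).  The denominator is always a net-flux expression.
    """
    problem = _Problem(model)
    split = _SplitProblem(problem)
    nv = split.n_vars
    # variables: [split fluxes y (nv), t]
    A_ub_x, b_ub_x, A_eq_x, b_eq_x = problem.constraint_rows(extra_constraints)

    eq_rows, eq_rhs = [], []
    S = problem.S.toarray()
    for i in range(S.shape[0]):
        eq_rows.append(np.append(split.lift(S[i]), 0.0))
        eq_rhs.append(0.0)
    for row, r in zip(A_eq_x, b_eq_x):
        eq_rows.append(np.append(split.lift(row), -r))
        eq_rhs.append(0.0)
    den_row = np.append(split.lift(problem.expression_vector(denominator)), 0.0)
    eq_rows.append(den_row)
    eq_rhs.append(1.0)

    ub_rows, ub_rhs = [], []
    for row, r in zip(A_ub_x, b_ub_x):
        ub_rows.append(np.append(split.lift(row), -r))
        ub_rhs.append(0.0)
    # scaled variable bounds: 0 <= y_j <= t * ub_j  (split vars are >= 0)
    lo_split = np.zeros(nv)
    hi_split = np.zeros(nv)
    for j in range(split.n_net):
        hi_split[j] = max(0.0, problem.ub[j])
        lo_split[j] = max(0.0, problem.lb[j])
    for j in split.rev_cols:
        hi_split[split.rev_pos[j]] = max(0.0, -problem.lb[j])
    for j in range(nv):
        row = np.zeros(nv + 1)
        row[j] = 1.0
        row[nv] = -hi_split[j]
        ub_rows.append(row); ub_rhs.append(0.0)
        if lo_split[j] > 0:
            row = np.zeros(nv + 1)
            row[j] = -1.0
            row[nv] = lo_split[j]
            ub_rows.append(row); ub_rhs.append(0.0)

    if isinstance(numerator, tuple):
        fwd, rev = numerator
        c = np.zeros(nv + 1)
        for rid, w in fwd.items():
            c[problem.ridx[rid]] += w
        for rid, w in rev.items():
            j = problem.ridx[rid]
            if j in split.rev_pos:
                c[split.rev_pos[j]] += w
    else:
        c = np.append(split.lift(problem.expression_vector(numerator)), 0.0)

    bounds = [(0.0, None)] * (nv + 1)
    status, x, ratio = backend.solve(
        c, np.array(eq_rows), np.array(eq_rhs),
        np.array(ub_rows) if ub_rows else None,
        np.array(ub_rhs) if ub_rows else None, bounds)
    if status != "optimal":
        return FluxDistribution(model_id=model.id, flux={}, objective_value=float("nan"),
                                status=status, meta={"method": "fractional"})
    t = x[nv]
    if t <= 1e-12:
        raise LPError("degenerate fractional program: t* = 0 (unbounded growth direction)")
    v = split.recombine(x[:nv]) / t
    return FluxDistribution(
        model_id=model.id, flux=dict(zip(problem.rids, v)),
        objective_value=float(ratio), status="optimal",
        meta={"method": "fractional", "t": float(t)},
    )


def apply_knockout(model: MetabolicModel, reaction_ids) -> MetabolicModel:
    """Copy of *model* with the given reactions' bounds set to (0, 0)."""
    ids = list(reaction_ids)
    unknown = [rid for rid in ids if rid not in model.rxn]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    ko = model.copy()
    for rid in ids:
        rxn = ko.rxn[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return ko
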