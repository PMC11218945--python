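"""Thin LP/MILP layer over optlang's GLPK interface.

One :class:`FluxProblem` instance wraps an optlang model holding a flux
variable per reaction and a mass-balance constraint per metabolite
(``S^c v = 0``).  Feasibility programs mutate variable bounds or add
constraints inside :meth:`scoped`, which restores the model afterwards, so one
problem object can serve many solves with deterministic variable ordering.
"""

from __future__ import annotations

from contextlib import contextmanager

from optlang.glpk_interface import Constraint, Model, Objective, Variable

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"

#: solver statuses that certify an empty feasible set
_INFEASIBLE_STATUSES = {"infeasible", "integer infeasible", "undefined"}


class SolverError(RuntimeError):
    """Raised when the solver neither proves feasibility nor infeasibility."""


class FluxProblem:
    """LP over the flux cone C = {v | S v = 0, lb <= v <= ub} of a community."""

    def __init__(self, reactions, tolerance: float = 1e-9):
        """``reactions``: iterable of objects with id/lower_bound/upper_bound/
        stoichiometry (sparse column dict metabolite -> coefficient)."""
        self.tolerance = tolerance
        self.model = Model(name="flux_cone")
        self.variables: dict[str, Variable] = {}
        balance: dict[str, list[tuple[Variable, float]]] = {}
        for rxn in reactions:
            v = Variable(rxn.id, lb=rxn.lower_bound, ub=rxn.upper_bound)
            self.variables[rxn.id] = v
            for met, coef in rxn.stoichiometry.items():
                if coef != 0:
                    balance.setdefault(met, []).append((v, coef))
        constraints = []
        for met in balance:
            expr = sum(coef * var for var, coef in balance[met])
            constraints.append(Constraint(expr, lb=0, ub=0, name=f"mb__{met}"))
        self.model.add(constraints)
        self.model.objective = Objective(0, direction="max")
        self._base_bounds = {
            rid: (v.lb, v.ub) for rid, v in self.variables.items()
        }

    # -- scoped modifications ---------------------------------------------

    @contextmanager
    def scoped(self):
        """Context manager undoing bound changes and added constraints/variables."""
        saved = {rid: (v.lb, v.ub) for rid, v in self.variables.items()}
        added_cons: list[Constraint] = []
        added_vars: list[Variable] = []
        try:
            yield _Scope(self, added_cons, added_vars)
        finally:
            if added_cons:
                self.model.remove(added_cons)
            if added_vars:
                self.model.remove(added_vars)
            for rid, (lb, ub) in saved.items():
                v = self.variables[rid]
                # set in an order that never inverts the interval
                if lb > v.ub:
                    v.ub = ub
                    v.lb = lb
                else:
                    v.lb = lb
                    v.ub = ub

    # -- bound edits (used inside scoped) ---------------------------------

    def fix(self, rxn_id: str, value: float = 0.0) -> None:
        v = self.variables[rxn_id]
        if value >= v.lb:
            v.ub = value
            v.lb = value
        else:
            v.lb = value
            v.ub = value

    def set_lower(self, rxn_id: str, lb: float) -> None:
        self.variables[rxn_id].lb = lb

    def set_upper(self, rxn_id: str, ub: float) -> None:
        self.variables[rxn_id].ub = ub

    # -- solves ------------------------------------------------------------

    def _solve(self) -> str:
        status = self.model.optimize()
        if status == OPTIMAL or status == "feasible":
            return OPTIMAL
        if status in _INFEASIBLE_STATUSES or status == "unbounded":
            # unbounded feasibility programs are feasible; only the objective
            # diverges.  With a zero objective GLPK never reports unbounded,
            # and box bounds keep optimisation objectives finite.
            return INFEASIBLE if status != "unbounded" else OPTIMAL
        raise SolverError(f"solver returned status {status!r}")

    def is_feasible(self) -> bool:
        self.model.objective = Objective(0, direction="max")
        return self._solve() == OPTIMAL

    def optimize(self, rxn_id: str, direction: str = "max") -> float | None:
        """Optimal flux of one reaction, or None when infeasible."""
        self.model.objective = Objective(self.variables[rxn_id], direction=direction)
        status = self._solve()
        if status != OPTIMAL:
            return None
        return float(self.model.objective.value)

    def primal(self) -> dict[str, float]:
        return {rid: float(v.primal) for rid, v in self.variables.items()}


class _Scope:
    """Handle for adding temporary constraints/variables inside ``scoped``."""

    def __init__(self, problem: FluxProblem, cons: list, vars_: list):
        self._problem = problem
        self._cons = cons
        self._vars = vars_

    def add_constraint(self, expression, lb=None, ub=None, name: str | None = None) -> Constraint:
        con = Constraint(expression, lb=lb, ub=ub, name=name)
        self._problem.model.add([con])
        self._cons.append(con)
        return con

    def add_binary(self, name: str) -> Variable:
        var = Variable(name, type="binary")
        self._problem.model.add([var])
        self._vars.append(var)
        return var
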