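"""Thin linear-programming layer over scipy's HiGHS interface.

Builds the stoichiometric matrix of a reaction network and solves the
flux-balance LPs (max c'v s.t. Sv = 0, lb <= v <= ub) that every
constraint-based operation in the package reduces to.  HiGHS is
deterministic, which keeps phenotype calls near decision thresholds
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

#: LP feasibility tolerance passed to HiGHS
FEASIBILITY_TOL = 1e-9
#: fluxes below this magnitude are reported as zero (mmol/gDCW/h)
FLUX_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class LinearProblem:
    """Stoichiometric LP data for a reaction network."""

    reaction_ids: List[str]
    metabolite_ids: List[str]
    S: np.ndarray  # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray

    @property
    def index(self) -> Dict[str, int]:
        return {rid: j for j, rid in enumerate(self.reaction_ids)}


def build_problem(network) -> LinearProblem:
    """Assemble S, lb, ub from any object with a ``reactions`` mapping."""
    reaction_ids = list(network.reactions)
    met_ids: List[str] = []
    met_index: Dict[str, int] = {}
    for rxn in network.reactions.values():
        for m in rxn.stoichiometry:
            if m not in met_index:
                met_index[m] = len(met_ids)
                met_ids.append(m)
    S = np.zeros((len(met_ids), len(reaction_ids)))
    lb = np.zeros(len(reaction_ids))
    ub = np.zeros(len(reaction_ids))
    for j, rid in enumerate(reaction_ids):
        rxn = network.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for m, coeff in rxn.stoichiometry.items():
            S[met_index[m], j] = coeff
    return LinearProblem(reaction_ids, met_ids, S, lb, ub)


def solve(
    problem: LinearProblem,
    objective: Dict[str, float],
    sense: str = "max",
    extra_A_ub: Optional[np.ndarray] = None,
    extra_b_ub: Optional[Sequence[float]] = None,
) -> Tuple[str, float, np.ndarray]:
    """Solve max/min of a linear objective over the flux polytope.

    Returns ``(status, objective_value, flux_vector)``; on non-optimal
    status the value is nan and the vector empty.
    """
    n = len(problem.reaction_ids)
    c = np.zeros(n)
    idx = problem.index
    for rid, coeff in objective.items():
        c[idx[rid]] = coeff
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=problem.S,
        b_eq=np.zeros(problem.S.shape[0]),
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=np.column_stack([problem.lb, problem.ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return status, float("nan"), np.empty(0)
    return status, float(c @ res.x), np.asarray(res.x)


def flux_range(
    problem: LinearProblem,
    reaction_id: str,
    extra_A_ub: Optional[np.ndarray] = None,
    extra_b_ub: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """Min and max feasible flux of one reaction (optionally constrained)."""
    lo_status, lo, _ = solve(problem, {reaction_id: 1.0}, "min", extra_A_ub, extra_b_ub)
    hi_status, hi, _ = solve(problem, {reaction_id: 1.0}, "max", extra_A_ub, extra_b_ub)
    if lo_status != "optimal" or hi_status != "optimal":
        raise RuntimeError(f"FVA subproblem for {reaction_id} terminated {lo_status}/{hi_status}")
    return lo, hi
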