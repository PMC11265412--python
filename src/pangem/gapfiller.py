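"""Minimal-addition gapfilling of draft strain models.

A draft that cannot sustain biomass production on the defined medium is
repaired by adding template reactions it lacks.  The solver is a binary-
indicator MILP: one binary variable per candidate reaction gates that
reaction's flux bounds, and the objective minimises the (weighted) number of
added reactions subject to steady-state mass balance and a biomass-flux
floor.  On small instances the result is therefore certifiably minimal.  If
the MILP hits its time limit, a deterministic greedy pass (add everything,
then attempt single-reaction removals in lexicographic order) produces a
functional but not certified-minimal repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from . import lp
from .flux_analysis import DEFAULT_GROWTH_THRESHOLD, fba
from .model import Medium, PanReactome, StrainModel
from .qc import apply_medium

__all__ = ["GapfillResult", "gapfill", "verify_functionality"]


@dataclass
class GapfillResult:
    added_reactions: Set[str]
    growth_before: float
    growth_after: float
    status: str  # already_functional | filled | infeasible
    certified_minimal: bool = True
    model: Optional[StrainModel] = None  # repaired copy (input is never mutated)

    def to_dict(self) -> Dict[str, object]:
        return {
            "added_reactions": sorted(self.added_reactions),
            "growth_before": self.growth_before,
            "growth_after": self.growth_after,
            "status": self.status,
            "certified_minimal": self.certified_minimal,
        }


def verify_functionality(
    model: StrainModel,
    medium: Medium,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    ngam: float = 1.0,
) -> bool:
    """True iff the FBA biomass optimum strictly exceeds the growth threshold."""
    solution = fba(model, medium, ngam=ngam)
    if solution.status not in ("optimal", "infeasible"):
        raise RuntimeError(f"solver failure ({solution.status}) on model {model.strain_id}")
    return solution.status == "optimal" and solution.objective_value > growth_threshold


def _with_reactions(model: StrainModel, reactome: PanReactome, extra: List[str],
                    provenance: str = "gapfilled") -> StrainModel:
    repaired = model.copy()
    repaired.metabolites = reactome.metabolites
    for rid in extra:
        repaired.reactions[rid] = reactome.reactions[rid].copy()
        repaired.provenance[rid] = provenance
    return repaired


def gapfill(
    model: StrainModel,
    reactome: PanReactome,
    medium: Medium,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    ngam: float = 1.0,
    weights: Optional[Dict[str, float]] = None,
    time_limit: float = 60.0,
) -> GapfillResult:
    """Add a minimum-cardinality set of template reactions restoring growth.

    Candidates are exactly the template reactions absent from the model, so a
    reaction already present can never be added.  ``weights`` optionally
    assigns per-candidate costs (uniform 1.0 by default).  The input model is
    never mutated; the repaired copy is returned on the result.
    """
    before = fba(model, medium, ngam=ngam)
    growth_before = before.objective_value if before.status == "optimal" else 0.0
    if growth_before > growth_threshold:
        return GapfillResult(set(), growth_before, growth_before,
                             "already_functional", True, model.copy())

    candidates = sorted(rid for rid in reactome.reactions if rid not in model.reactions)
    full = _with_reactions(model, reactome, candidates)
    if not verify_functionality(full, medium, growth_threshold, ngam):
        return GapfillResult(set(), growth_before, growth_before, "infeasible", True, None)

    added = _milp_minimal_addition(
        model, reactome, candidates, medium, growth_threshold, ngam, weights, time_limit
    )
    certified = added is not None
    if added is None:
        added = _greedy_fallback(model, reactome, candidates, medium, growth_threshold, ngam)
    repaired = _with_reactions(model, reactome, sorted(added))
    after = fba(repaired, medium, ngam=ngam)
    return GapfillResult(
        added_reactions=set(added),
        growth_before=growth_before,
        growth_after=after.objective_value,
        status="filled",
        certified_minimal=certified,
        model=repaired,
    )


def _milp_minimal_addition(
    model: StrainModel,
    reactome: PanReactome,
    candidates: List[str],
    medium: Medium,
    growth_threshold: float,
    ngam: float,
    weights: Optional[Dict[str, float]],
    time_limit: float,
) -> Optional[List[str]]:
    """Solve the indicator MILP; None on timeout/solver failure."""
    full = _with_reactions(model, reactome, candidates)
    constrained = apply_medium(full, medium, ngam=ngam)
    problem = lp.build_problem(constrained)
    n = len(problem.reaction_ids)
    m = len(candidates)
    idx = problem.index

    c = np.zeros(n + m)
    for j, rid in enumerate(candidates):
        c[n + j] = (weights or {}).get(rid, 1.0)

    rows: List[np.ndarray] = []
    lbs: List[float] = []
    ubs: List[float] = []

    # steady state: S v = 0
    A_eq = np.hstack([problem.S, np.zeros((problem.S.shape[0], m))])
    rows.append(A_eq)
    lbs.extend([0.0] * A_eq.shape[0])
    ubs.extend([0.0] * A_eq.shape[0])

    # candidate gating: lb_k * y_j <= v_k <= ub_k * y_j
    gate = np.zeros((2 * m, n + m))
    gate_lb = np.full(2 * m, -np.inf)
    gate_ub = np.zeros(2 * m)
    for j, rid in enumerate(candidates):
        k = idx[rid]
        gate[2 * j, k] = 1.0
        gate[2 * j, n + j] = -problem.ub[k]          # v_k - ub*y <= 0
        gate[2 * j + 1, k] = -1.0
        gate[2 * j + 1, n + j] = problem.lb[k]       # lb*y - v_k <= 0
    rows.append(gate)
    lbs.extend(gate_lb.tolist())
    ubs.extend(gate_ub.tolist())

    # biomass floor, with a small margin so the repaired optimum is strictly
    # above the growth threshold
    margin = max(1e-9, 1e-4 * growth_threshold)
    bio = np.zeros((1, n + m))
    bio[0, idx[model.biomass_id]] = 1.0
    rows.append(bio)
    lbs.append(growth_threshold + margin)
    ubs.append(np.inf)

    A = np.vstack(rows)
    var_lb = np.concatenate([problem.lb, np.zeros(m)])
    var_ub = np.concatenate([problem.ub, np.ones(m)])
    integrality = np.concatenate([np.zeros(n), np.ones(m)])

    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(lbs), np.array(ubs)),
        bounds=OptBounds(var_lb, var_ub),
        integrality=integrality,
        options={"time_limit": time_limit, "mip_rel_gap": 0.0},
    )
    if not res.success:
        return None
    y = res.x[n:]
    return [candidates[j] for j in range(m) if y[j] > 0.5]


def _greedy_fallback(
    model: StrainModel,
    reactome: PanReactome,
    candidates: List[str],
    medium: Medium,
    growth_threshold: float,
    ngam: float,
) -> List[str]:
    """Deterministic set-minimal (not cardinality-minimal) repair."""
    kept = list(candidates)
    for rid in sorted(candidates):
        trial = [r for r in kept if r != rid]
        trial_model = _with_reactions(model, reactome, trial)
        if verify_functionality(trial_model, medium, growth_threshold, ngam):
            kept = trial
    return kept
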