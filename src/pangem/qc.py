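"""Quality control of the template network and medium application.

Covers the three structural checks a template reactome must pass before it
can seed strain reconstructions — elemental/charge balance of every chemical
reaction, absence of thermodynamically infeasible cycles (TICs), and a
consistent reaction-type taxonomy — plus the bound bookkeeping that turns a
chemically defined medium into exchange-reaction constraints.
"""

from __future__ import annotations

import warnings
from collections import Counter
from fractions import Fraction
from typing import Dict, List, Optional, Set, Tuple, Union

import numpy as np

from . import lp
from .model import (
    DEFAULT_BOUND,
    Medium,
    PanReactome,
    StrainModel,
    ValidationError,
    has_pseudo_elements,
    stoichiometry_as_fractions,
)

__all__ = [
    "check_mass_charge_balance",
    "detect_infeasible_cycles",
    "classify_reaction_types",
    "apply_medium",
]

#: reaction types exempt from balance checking (boundary / pseudo reactions)
BALANCE_EXEMPT = frozenset({"exchange", "demand", "sink", "biomass"})

#: flux magnitude above which a closed-exchange FVA range flags a TIC
TIC_FLUX_TOL = 1e-6

Network = Union[PanReactome, StrainModel]


def check_mass_charge_balance(reactome: Network) -> List[Tuple[str, str, float]]:
    """Report every elemental or charge imbalance in the chemical reactions.

    Exchange, demand, sink and biomass reactions are boundary/pseudo reactions
    and exempt; reactions touching a metabolite with a pseudo-element formula
    (R-groups) are exempted with a warning.  Balances are computed in exact
    rational arithmetic, so an empty return certifies the network balanced.

    Returns a list of ``(reaction_id, element_or_"charge", imbalance)``.
    """
    report: List[Tuple[str, str, float]] = []
    for rxn in reactome.reactions.values():
        if rxn.rtype in BALANCE_EXEMPT:
            continue
        mets = [reactome.metabolites[m] for m in rxn.stoichiometry]
        for met in mets:
            if met.formula is None or met.charge is None:
                raise ValidationError(
                    f"metabolite {met.id} in reaction {rxn.id} lacks formula or charge"
                )
        if any(has_pseudo_elements(m.formula) for m in mets):
            warnings.warn(
                f"reaction {rxn.id} touches a pseudo-element metabolite; "
                "exempted from balance checking",
                stacklevel=2,
            )
            continue
        coeffs = stoichiometry_as_fractions(rxn)
        totals: Dict[str, Fraction] = {}
        charge = Fraction(0)
        for met in mets:
            c = coeffs[met.id]
            for element, count in met.element_counts().items():
                totals[element] = totals.get(element, Fraction(0)) + c * count
            charge += c * met.charge
        for element in sorted(totals):
            if totals[element] != 0:
                report.append((rxn.id, element, float(totals[element])))
        if charge != 0:
            report.append((rxn.id, "charge", float(charge)))
    return report


def detect_infeasible_cycles(reactome: Network, tol: float = TIC_FLUX_TOL) -> Set[str]:
    """Reactions able to carry flux with every exchange closed (TIC members).

    Runs objective-free flux variability with both bounds of every exchange
    reaction set to zero; any internal reaction whose flux range exceeds
    ``tol`` can only be fed by a thermodynamically infeasible internal loop.
    An empty set certifies the network TIC-free.
    """
    closed = _copy_network(reactome)
    for rxn in closed.reactions.values():
        if rxn.rtype == "exchange":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        else:
            # relax forced fluxes (e.g. the NGAM demand) so v = 0 is feasible
            rxn.lower_bound = min(rxn.lower_bound, 0.0)
            rxn.upper_bound = max(rxn.upper_bound, 0.0)
    problem = lp.build_problem(closed)
    cyclic: Set[str] = set()
    for rid in problem.reaction_ids:
        if closed.reactions[rid].rtype == "exchange":
            continue
        lo, hi = lp.flux_range(problem, rid)
        if abs(lo) > tol or abs(hi) > tol:
            cyclic.add(rid)
    return cyclic


def classify_reaction_types(reactome: Network) -> Dict[str, int]:
    """Count reactions per type; counts partition the reaction set."""
    return dict(Counter(rxn.rtype for rxn in reactome.reactions.values()))


def apply_medium(
    model: Network,
    medium: Medium,
    ngam: float = 1.0,
    strict: bool = True,
    bound_cap: float = DEFAULT_BOUND,
) -> Network:
    """Return a copy of ``model`` constrained to the medium.

    Every exchange listed in the medium gets lower bound ``-uptake`` (capped
    at the network's declared bound magnitude); every exchange *not* listed is
    closed to uptake (lower bound 0).  Secretion upper bounds are untouched.
    The NGAM lower bound is enforced at ``ngam`` mmol/gDCW/h.

    With ``strict`` (default), a medium id with no matching exchange reaction
    raises; otherwise it is ignored.
    """
    constrained = _copy_network(model)
    exchange_ids = {r.id for r in constrained.reactions.values() if r.rtype == "exchange"}
    unknown = set(medium.uptake_limits) - exchange_ids
    if unknown and strict:
        raise ValidationError(
            f"medium {medium.name} lists unknown exchange reactions: {sorted(unknown)}"
        )
    for rid in exchange_ids:
        rxn = constrained.reactions[rid]
        uptake = medium.uptake_limits.get(rid, 0.0)
        cap = max(bound_cap, abs(model.reactions[rid].lower_bound))
        rxn.lower_bound = -min(uptake, cap)
    ngam_rxn = constrained.reactions[constrained.ngam_id]
    ngam_rxn.lower_bound = ngam
    if ngam_rxn.upper_bound < ngam:
        ngam_rxn.upper_bound = ngam
    return constrained


def _copy_network(network: Network) -> Network:
    return network.copy()
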