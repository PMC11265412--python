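"""Constraint-based phenotyping: FBA, FVA and the derived phenotype calls.

All simulations maximise the biomass reaction subject to steady-state mass
balance (Sv = 0) and flux bounds, with the medium applied first (uptake
limits on exchanges, everything unlisted closed to uptake, NGAM enforced).
Phenotype thresholds follow the growth-call convention: growth is reported
when the predicted rate strictly exceeds ``growth_threshold`` (0.01/h by
default) and auxotrophy when the rate on single omission falls strictly
below it; a rate exactly at the threshold is neither and is logged as
indeterminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from . import lp
from .model import Medium, StrainModel
from .qc import apply_medium

__all__ = [
    "FluxSolution",
    "FVAResult",
    "EssentialityProfile",
    "FermentationProfile",
    "fba",
    "fva",
    "carbon_source_growth",
    "single_omission_essentiality",
    "fermentation_profile",
    "core_fluxome",
]

logger = logging.getLogger(__name__)

DEFAULT_GROWTH_THRESHOLD = 0.01  # 1/h
SECRETION_TOL = 1e-6  # mmol/gDCW/h


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: Dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def grows(self) -> bool:
        return self.status == "optimal" and self.objective_value > DEFAULT_GROWTH_THRESHOLD


@dataclass
class FVAResult:
    ranges: Dict[str, Tuple[float, float]]
    fraction_of_optimum: float


@dataclass
class EssentialityProfile:
    strain_id: str
    verdicts: Dict[str, str]  # exchange id -> essential | non_essential
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD

    @property
    def essential(self) -> Set[str]:
        return {c for c, v in self.verdicts.items() if v == "essential"}


@dataclass
class FermentationProfile:
    strain_id: str
    secreted: Set[str]
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def _prepared_problem(model: StrainModel, medium: Optional[Medium], ngam: float):
    constrained = apply_medium(model, medium, ngam=ngam) if medium is not None else model
    return lp.build_problem(constrained)


def fba(model: StrainModel, medium: Optional[Medium] = None, ngam: float = 1.0) -> FluxSolution:
    """Maximise biomass flux; returns the optimum and one optimal flux vector."""
    problem = _prepared_problem(model, medium, ngam)
    status, value, x = lp.solve(problem, {model.biomass_id: 1.0}, "max")
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status)
    fluxes = {rid: (0.0 if abs(v) < lp.FLUX_TOL else float(v))
              for rid, v in zip(problem.reaction_ids, x)}
    return FluxSolution(float(value), fluxes, "optimal")


def fva(
    model: StrainModel,
    medium: Optional[Medium] = None,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    ngam: float = 1.0,
) -> FVAResult:
    """Per-reaction min/max flux subject to biomass >= fraction x optimum."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    problem = _prepared_problem(model, medium, ngam)
    status, optimum, _ = lp.solve(problem, {model.biomass_id: 1.0}, "max")
    if status != "optimal":
        raise RuntimeError(f"base FBA for {model.strain_id} terminated {status}")
    n = len(problem.reaction_ids)
    row = np.zeros((1, n))
    row[0, problem.index[model.biomass_id]] = -1.0
    b = [-fraction_of_optimum * optimum]
    targets = list(reactions) if reactions is not None else list(problem.reaction_ids)
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        lo, hi = lp.flux_range(problem, rid, extra_A_ub=row, extra_b_ub=b)
        if lo > hi:  # numerically pinched interval
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return FVAResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


def carbon_source_growth(
    model: StrainModel,
    medium: Medium,
    csource_exchange: str,
    primary_exchange: str,
    uptake: float = 1000.0,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    ngam: float = 1.0,
) -> bool:
    """Growth call on an alternative carbon source.

    The primary carbon source's uptake is closed, the target source's uptake
    opened to ``uptake`` mmol/gDCW/h, and biomass maximised; growth is
    reported iff the optimum strictly exceeds the threshold.  A carbon source
    whose exchange reaction is absent from the strain cannot be consumed and
    returns False immediately.
    """
    if csource_exchange not in model.reactions:
        return False
    limits = dict(medium.uptake_limits)
    limits[primary_exchange] = 0.0
    limits[csource_exchange] = uptake
    solution = fba(model, Medium(limits, name=f"csource-{csource_exchange}"), ngam=ngam)
    if solution.status != "optimal":
        return False
    if solution.objective_value == growth_threshold:
        logger.warning(
            "strain %s on %s: growth rate exactly at threshold; calling no-growth",
            model.strain_id, csource_exchange,
        )
    return solution.objective_value > growth_threshold


def single_omission_essentiality(
    model: StrainModel,
    medium: Medium,
    components: Optional[Sequence[str]] = None,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    ngam: float = 1.0,
) -> EssentialityProfile:
    """Single-omission analysis over medium components.

    Each component's uptake is set to zero in turn (the medium is restored
    between tests); the component is essential for the strain iff the
    resulting optimum falls strictly below the growth threshold.
    """
    baseline = fba(model, medium, ngam=ngam)
    if baseline.status != "optimal" or baseline.objective_value <= growth_threshold:
        raise RuntimeError(
            f"strain {model.strain_id} does not grow on the full medium "
            f"(status {baseline.status}); omission results undefined"
        )
    if components is None:
        components = sorted(medium.uptake_limits)
    verdicts: Dict[str, str] = {}
    for component in components:
        solution = fba(model, medium.without(component), ngam=ngam)
        rate = solution.objective_value if solution.status == "optimal" else 0.0
        if rate == growth_threshold:
            logger.warning(
                "strain %s omitting %s: rate exactly at threshold; calling non-essential",
                model.strain_id, component,
            )
        verdicts[component] = "essential" if rate < growth_threshold else "non_essential"
    return EssentialityProfile(model.strain_id, verdicts, growth_threshold)


def fermentation_profile(
    model: StrainModel,
    medium: Medium,
    fva_fraction: float = 1.0,
    ngam: float = 1.0,
    secretion_tol: float = SECRETION_TOL,
) -> FermentationProfile:
    """Secreted-byproduct profile: exchanges with positive flux at optimum.

    ``secreted`` is the set of exchange reactions with FBA flux above the
    secretion tolerance; ``ranges`` gives each exchange's FVA interval at
    ``fva_fraction`` of the optimum, which is the degeneracy-free statement
    of what the strain can secrete.
    """
    solution = fba(model, medium, ngam=ngam)
    if solution.status != "optimal" or solution.objective_value <= DEFAULT_GROWTH_THRESHOLD:
        raise RuntimeError(f"strain {model.strain_id} does not grow on {medium.name}")
    exchange_ids = sorted(r.id for r in model.reactions.values() if r.rtype == "exchange")
    secreted = {rid for rid in exchange_ids if solution.fluxes.get(rid, 0.0) > secretion_tol}
    ranges = fva(model, medium, fraction_of_optimum=fva_fraction,
                 reactions=exchange_ids, ngam=ngam).ranges
    return FermentationProfile(model.strain_id, secreted, ranges)


def core_fluxome(
    models: Sequence[StrainModel],
    medium: Union[Medium, Mapping[str, Medium]],
    core_reactions: Iterable[str],
    fva_fraction: float = 1.0,
    ngam: float = 1.0,
    flux_tol: float = lp.FLUX_TOL,
) -> Dict[str, Dict[str, object]]:
    """Activity and growth-correlation of core reactions across strains.

    For each core reaction, reports whether it is active (non-zero FVA range)
    in every strain and the Pearson correlation between its per-strain
    maximum flux and the per-strain growth rate.  Reactions whose maximum
    flux does not vary across strains have an undefined correlation and are
    reported with ``r=None`` rather than a fabricated value.

    ``medium`` may be one Medium for all strains or a per-strain mapping
    (e.g. when growth diversity comes from strain-specific uptake limits).
    """
    models = list(models)
    if len(models) < 3:
        raise ValueError("core_fluxome needs at least 3 strains for a stable correlation")
    core = list(core_reactions)

    def medium_for(m: StrainModel) -> Medium:
        return medium[m.strain_id] if isinstance(medium, Mapping) else medium

    growth: List[float] = []
    max_flux: Dict[str, List[float]] = {rid: [] for rid in core}
    active: Dict[str, bool] = {rid: True for rid in core}
    for model in models:
        missing = [rid for rid in core if rid not in model.reactions]
        if missing:
            raise ValueError(f"strain {model.strain_id} lacks core reactions {missing}")
        med = medium_for(model)
        solution = fba(model, med, ngam=ngam)
        if solution.status != "optimal" or solution.objective_value <= DEFAULT_GROWTH_THRESHOLD:
            raise RuntimeError(f"strain {model.strain_id} does not grow on {med.name}")
        growth.append(solution.objective_value)
        ranges = fva(model, med, fraction_of_optimum=fva_fraction,
                     reactions=core, ngam=ngam).ranges
        for rid, (lo, hi) in ranges.items():
            max_flux[rid].append(hi)
            if abs(lo) <= flux_tol and abs(hi) <= flux_tol:
                active[rid] = False

    g = np.asarray(growth)
    out: Dict[str, Dict[str, object]] = {}
    for rid in core:
        f = np.asarray(max_flux[rid])
        if np.ptp(f) <= flux_tol or np.ptp(g) <= flux_tol:
            r: Optional[float] = None
        else:
            r = float(np.corrcoef(f, g)[0, 1])
        out[rid] = {"active_in_all": active[rid], "r": r, "max_flux": f.tolist()}
    return out
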